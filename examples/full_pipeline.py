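"""Run the whole analysis on a synthetic genus table and plot diagnostics.

Generates the default era-partitioned dataset (113/386/392 genera in the
5-archetype pyramid with planted diameter effects), runs every stage —
era triangles, Pareto front, pyramid fit, size enrichment, Westermann
projection — and writes the report plus two figures.
"""

import json
from pathlib import Path

from ammopareto import (
    GridSpec,
    MorphoDataset,
    Polytope,
    make_dataset,
    run_full_analysis,
)
from ammopareto.plotting import plot_morphospace, plot_rms_profile

out = Path("pipeline_output")
ds = MorphoDataset(table=make_dataset())
grid = GridSpec(axes={"D": (0.0, 0.95, 61), "W": (1 + 1e-6, 5.0, 61)},
                fixed={"S": 1.0})
bundle = run_full_analysis(ds, seed=0, n_null=200, grid=grid,
                           k_range=range(2, 7), pcha_restarts=4, out_dir=out)

tri = bundle["stages"]["triangles"]
for era, r in tri["per_era"].items():
    print(f"{era:>8}: t-ratio {r['t_ratio']:.3f} (p = {r['p_polygonality']:.3g})")
print("triangle IoU:", {k: round(v, 2) for k, v in tri["similarity"].items()})
print("pyramid RMS profile:",
      {k: round(v, 3) for k, v in bundle["stages"]["pyramid"]["rms_profile"].items()})
for v, r in bundle["stages"]["enrichment"].items():
    print(f"{v}: slope {r['slope']:+.2f} p {r['p_value']:.3g} -> {r['direction']}")

# figures
import matplotlib.pyplot as plt

era0 = ds.table[ds.table["era"] == "post-PT"]
ax = plot_morphospace(
    era0[["D", "W"]].to_numpy(),
    Polytope(__import__("numpy").array(tri["per_era"]["post-PT"]["vertices_DW"]),
             kind="simplex"),
    label="post-PT genera",
)
ax.figure.savefig(out / "morphospace.png", dpi=120)
ax2 = plot_rms_profile({int(k): v for k, v in
                        bundle["stages"]["pyramid"]["rms_profile"].items()})
ax2.figure.savefig(out / "rms_profile.png", dpi=120, bbox_inches="tight")
print(f"\nreport and figures in {out}/")
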