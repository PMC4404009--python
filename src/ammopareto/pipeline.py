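"""Full analysis pipeline: triangles per era, Pareto front, pyramid, sizes.

:func:`run_full_analysis` orchestrates the whole study on one dataset:

1. per-era triangle fits in the (D, W) plane with polygonality tests and
   pairwise triangle-similarity tests,
2. performance surfaces and the Pareto front on the (D, W) grid,
3. PCHA RMS profile over vertex counts and the 5-vertex pyramid fit
   (3-trait data only),
4. diameter enrichment at each fitted vertex (if diameters are present),
5. Westermann projection of the fitted vertices with sensitivity regions.

Every stage draws its seed from a master seed, all numbers are returned
in a JSON-serialisable bundle, and stage failures are isolated.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np

from .archetype_fit import fit_pcha, fit_simplex, rms_profile
from .dataset import MorphoDataset
from .morphostats import (
    enrichment_by_distance,
    polygonality_test,
    triangle_similarity,
)
from .pareto import front_on_grid
from .performance import (
    DEFAULT_GRID_2D,
    GridSpec,
    drag_performance,
    economy_performance,
    growth_performance,
)
from .westermann import sensitivity_region, to_westermann

log = logging.getLogger("ammopareto")

__all__ = ["run_full_analysis"]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def run_full_analysis(
    dataset: MorphoDataset,
    seed: int = 0,
    n_null: int = 200,
    grid: GridSpec | None = None,
    k_range=range(2, 9),
    pcha_restarts: int = 8,
    out_dir: str | Path | None = None,
) -> dict:
    """Run all analysis stages on a dataset; returns the report bundle.

    ``n_null`` controls every randomisation test (the study-scale value is
    10,000; smaller values keep exploratory runs fast).  If ``out_dir`` is
    given the bundle is also written to ``report.json`` there.
    """
    rng = np.random.default_rng(seed)
    stage_seed = {
        name: int(rng.integers(2**31 - 1))
        for name in ("triangles", "pareto", "pyramid", "enrichment", "westermann")
    }
    bundle: dict = {"seed": seed, "stage_seeds": stage_seed, "n_rows": len(dataset),
                    "stages": {}, "incomplete": []}

    def run_stage(name, fn):
        t0 = time.perf_counter()
        try:
            bundle["stages"][name] = fn()
            log.info("stage %s done in %.2fs (seed %d)", name,
                     time.perf_counter() - t0, stage_seed[name])
        except Exception as exc:   # noqa: BLE001 - stage isolation is the contract
            bundle["incomplete"].append(name)
            bundle["stages"][name] = {"error": f"{type(exc).__name__}: {exc}"}
            log.warning("stage %s failed: %s", name, exc)

    # ---- stage 1: per-era triangles ------------------------------------
    def triangles():
        srng = np.random.default_rng(stage_seed["triangles"])
        out = {"per_era": {}, "similarity": {}}
        fits = {}
        for era, sub in dataset.by_era().items():
            pts = sub[["D", "W"]].to_numpy(float)
            fit = fit_simplex(pts, seed=int(srng.integers(2**31 - 1)))
            test = polygonality_test(
                pts, n_null=n_null, seed=int(srng.integers(2**31 - 1)),
                fit_kwargs=dict(maxiter=600),
            )
            fits[era] = fit
            out["per_era"][era] = {
                "n": len(pts),
                "vertices_DW": fit.polytope.vertices.tolist(),
                "t_ratio": test.statistic,
                "p_polygonality": test.p_value,
                "rms_error": fit.rms_error,
                "fraction_inside": fit.fraction_inside,
            }
        eras = list(fits)
        for i, ea in enumerate(eras):
            for eb in eras[i + 1:]:
                r = triangle_similarity(fits[ea].polytope, fits[eb].polytope)
                out["similarity"][f"{ea}|{eb}"] = r
        return out

    run_stage("triangles", triangles)

    # ---- stage 2: performance surfaces + Pareto front ------------------
    def pareto_stage():
        g = grid or DEFAULT_GRID_2D
        surfaces = [economy_performance(), growth_performance(), drag_performance()]
        front = front_on_grid(surfaces, g)
        return {
            "n_grid": len(front.points),
            "n_front": int(front.mask.sum()),
            "archetypes": front.archetypes.to_dict(orient="records"),
        }

    run_stage("pareto", pareto_stage)

    # ---- stage 3: pyramid (3-trait data only) --------------------------
    pyramid_fit = None

    def pyramid():
        nonlocal pyramid_fit
        if not dataset.has_S:
            return {"skipped": "no S column; 3-D stages need (D, S, W)"}
        X = dataset.traits()
        profile = rms_profile(X, k_range=k_range, restarts=pcha_restarts,
                              seed=stage_seed["pyramid"])
        pyramid_fit = fit_pcha(X, k=5, restarts=pcha_restarts,
                               seed=stage_seed["pyramid"])
        return {
            "rms_profile": {str(k): v for k, v in profile.items()},
            "vertices_DSW": pyramid_fit.polytope.vertices.tolist(),
            "rms_error": pyramid_fit.rms_error,
            "fraction_inside": pyramid_fit.fraction_inside,
            "converged": pyramid_fit.converged,
        }

    run_stage("pyramid", pyramid)

    # ---- stage 4: diameter enrichment ----------------------------------
    def enrichment():
        if not dataset.has_diameter:
            return {"skipped": "no diameter_cm column"}
        if pyramid_fit is None:
            return {"skipped": "no pyramid fit available"}
        X = dataset.traits()
        y = dataset.table["diameter_cm"].to_numpy(float)
        ok = np.isfinite(y) & (y > 0)
        out = {}
        for i, v in enumerate(pyramid_fit.polytope.vertices):
            res = enrichment_by_distance(
                X[ok], y[ok], v, n_perm=n_null, seed=stage_seed["enrichment"] + i
            )
            out[f"vertex_{i + 1}"] = {
                "slope": res.slope, "p_value": res.p_value,
                "direction": res.direction, "bin_means": res.bin_means.tolist(),
            }
        return out

    run_stage("enrichment", enrichment)

    # ---- stage 5: Westermann projection --------------------------------
    def westermann():
        if pyramid_fit is None:
            return {"skipped": "no pyramid fit available"}
        out = {}
        for i, v in enumerate(pyramid_fit.polytope.vertices):
            D, S, W = v
            try:
                tp = to_westermann((D, S, W))
                sens = sensitivity_region((D, S, W), seed=stage_seed["westermann"] + i)
                out[f"vertex_{i + 1}"] = {
                    "ternary": list(tp.coords),
                    "extrapolated": tp.extrapolated,
                    "max_spread": sens["max_spread"],
                    "n_undefined": sens["n_undefined"],
                }
            except ValueError as exc:
                out[f"vertex_{i + 1}"] = {"error": str(exc)}
        return out

    run_stage("westermann", westermann)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "report.json", "w") as fh:
            json.dump(_jsonable(bundle), fh, indent=2)
    return _jsonable(bundle)
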