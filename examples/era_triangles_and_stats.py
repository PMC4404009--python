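"""Per-era triangle fits with the polygonality and similarity tests.

Simulates an era-partitioned genus table (three intervals between mass
extinctions drawn from one triangle in the (D, W) plane), fits an
enclosing triangle to each era, tests how triangular each distribution is
against column-permuted nulls, and measures how similar the era triangles
are to each other (intersection-over-union, with a random-triangle null).
"""

import numpy as np

from ammopareto import (
    fit_simplex,
    polygonality_test,
    sample_polytope,
    similarity_test,
    triangle_similarity,
)

TRIANGLE = np.array([[0.0, 1.0], [0.7, 1.35], [0.0, 4.6]])
counts = {"FF-DM": 113, "DM-PT": 386, "post-PT": 392}

fits = {}
for i, (era, n) in enumerate(counts.items()):
    pts, _ = sample_polytope(TRIANGLE, n, concentration=0.8, noise_sd=0.02,
                             seed=10 + i)
    fit = fit_simplex(pts, seed=0)
    test = polygonality_test(pts, n_null=200, seed=i,
                             fit_kwargs=dict(maxiter=600))
    fits[era] = fit
    print(f"{era:>8}: n = {n:3d}  t-ratio = {test.statistic:.3f}  "
          f"p = {test.p_value:.3g}")

print("\npairwise triangle similarity (intersection / union):")
eras = list(fits)
for i, a in enumerate(eras):
    for b in eras[i + 1:]:
        iou = triangle_similarity(fits[a].polytope, fits[b].polytope)
        p = similarity_test(iou, n_null=2000, seed=3).p_value
        print(f"  {a} vs {b}: {iou:.2f}  (random-pair null p <= {p:.2g})")
print(
    "\nHigh t-ratios with small p say each era fills a genuinely "
    "triangular region; high pairwise similarity says the same region is "
    "refilled after each extinction."
)
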