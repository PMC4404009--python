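"""Recover a 5-vertex pyramid from synthetic genus data with PCHA.

Generates 1000 genera inside the default 5-archetype pyramid (Dirichlet
weights concentrated toward the corners so the vertices are identifiable,
2% trait noise), runs the error-versus-k profile and the k = 5 fit, and
compares the fitted archetypes with the planted ones.
"""

import numpy as np

from ammopareto import PYRAMID_VERTICES, fit_pcha, rms_profile, sample_polytope

pts, _ = sample_polytope(PYRAMID_VERTICES, 1000, concentration=0.25,
                         noise_sd=0.02, seed=4)

profile = rms_profile(pts, k_range=range(2, 8), restarts=4, seed=0)
print("RMS reconstruction error by number of archetypes:")
for k, v in sorted(profile.items()):
    print(f"  k = {k}: {v:.4f}")
print("-> the error collapses at k = 5 and barely improves beyond: "
      "five archetypes describe the data parsimoniously.\n")

rep = fit_pcha(pts, k=5, restarts=6, seed=0)
print("fitted archetypes (D, S, W) vs planted vertices:")
order = []
for v in rep.polytope.vertices:
    order.append(int(np.argmin(np.linalg.norm(PYRAMID_VERTICES - v, axis=1))))
for v, j in zip(rep.polytope.vertices, order):
    print(f"  fitted {np.round(v, 3)}   planted {PYRAMID_VERTICES[j]}")
print(f"\nRMS error {rep.rms_error:.4f} (standardised units), "
      f"{100 * rep.fraction_inside:.0f}% of genera inside the fitted polytope")
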