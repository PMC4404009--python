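"""Westermann-style ternary projection of (D, S, W) morphospace.

The Westermann morphospace maps each shell to a point in a triangle whose
corners correspond to serpenticone (umbilical exposure dominant), oxycone
(expansion dominant) and sphericone (inflation dominant) end members.  The
published diagrams do not fix a unique formula, so the mapping here is a
documented reconstruction: each trait is rescaled to a [0, 1] score by an
affine transform and the three scores are normalised to barycentric
coordinates.  Because of the normalisation the map is projective — shells
whose three scores are all small are mapped with large uncertainty, which
is exactly the warping quantified by :func:`sensitivity_region`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["TernaryPoint", "WestermannTransform", "to_westermann", "sensitivity_region"]

#: default affine normalisation ranges
W_REF = 5.0
S_REF = 3.5


@dataclass(frozen=True)
class TernaryPoint:
    """Barycentric coordinates (serpenticone, oxycone, sphericone)."""

    coords: tuple[float, float, float]
    extrapolated: bool = False     # any score negative before normalising

    def __post_init__(self) -> None:
        if abs(sum(self.coords) - 1.0) > 1e-9:
            raise ValueError("barycentric coordinates must sum to 1")

    def xy(self) -> tuple[float, float]:
        """Planar coordinates in the unit-edge ternary triangle."""
        u, o, s = self.coords
        return o + 0.5 * s, (np.sqrt(3) / 2.0) * s


@dataclass(frozen=True)
class WestermannTransform:
    """Affine score ranges for the ternary projection (all exposed)."""

    w_ref: float = W_REF
    s_ref: float = S_REF

    def scores(self, D: float, S: float, W: float) -> np.ndarray:
        return np.array([D, (W - 1.0) / (self.w_ref - 1.0), S / self.s_ref])


def to_westermann(
    point, transform: WestermannTransform | None = None
) -> TernaryPoint:
    """Map a (D, S, W) point to the ternary triangle.

    Scores: ``D`` as-is (umbilical exposure), ``(W - 1)/(w_ref - 1)``
    (expansion), ``S / s_ref`` (inflation); normalised by their sum.
    A point with all three scores zero has no defined direction and is
    rejected — this is the warped region near the low-D/S/W corner of
    morphospace.
    """
    tr = transform or WestermannTransform()
    D, S, W = (float(x) for x in point)
    sc = tr.scores(D, S, W)
    total = sc.sum()
    if abs(total) < 1e-12:
        raise ValueError("undefined ternary direction: all scores are zero")
    return TernaryPoint(tuple(sc / total), extrapolated=bool(np.any(sc < 0)))


def sensitivity_region(
    point,
    radius_frac: float = 0.05,
    n_samples: int = 500,
    seed: int | None = 0,
    trait_spans=(1.0, 3.4, 4.0),
    transform: WestermannTransform | None = None,
) -> dict:
    """Dispersion of the ternary image of a small morphospace ball.

    Samples ``n_samples`` points uniformly in a ball of radius
    ``radius_frac`` of the total trait variation (``trait_spans`` holds
    the (D, S, W) spans), maps each sample, and summarises the planar
    spread of the images: maximum pairwise distance, RMS distance to the
    centroid and the covariance matrix.  Samples that hit the undefined
    all-zero-score corner are counted and skipped.
    """
    if radius_frac < 0:
        raise ValueError("radius_frac must be >= 0")
    rng = np.random.default_rng(seed)
    center = np.asarray(point, dtype=float)
    spans = np.asarray(trait_spans, dtype=float)
    u = rng.standard_normal((n_samples, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    r = rng.random(n_samples) ** (1.0 / 3.0)
    samples = center + radius_frac * spans * u * r[:, None]
    samples[:, 0] = np.clip(samples[:, 0], 0.0, 0.999)     # keep D valid
    samples[:, 1] = np.maximum(samples[:, 1], 1e-6)        # S > 0
    xy, undefined = [], 0
    for s in samples:
        try:
            xy.append(to_westermann(s, transform).xy())
        except ValueError:
            undefined += 1
    xy = np.array(xy) if xy else np.empty((0, 2))
    if len(xy) < 2:
        return {"max_spread": np.nan, "rms_spread": np.nan,
                "covariance": np.full((2, 2), np.nan),
                "n_mapped": len(xy), "n_undefined": undefined}
    centroid = xy.mean(axis=0)
    d2 = np.sum((xy - centroid) ** 2, axis=1)
    # max pairwise distance via hull-ish bound: exact O(n^2) is fine at n=500
    diff = xy[:, None, :] - xy[None, :, :]
    maxp = float(np.sqrt(np.max(np.sum(diff**2, axis=2))))
    return {
        "max_spread": maxp,
        "rms_spread": float(np.sqrt(d2.mean())),
        "covariance": np.cov(xy.T),
        "n_mapped": len(xy),
        "n_undefined": undefined,
    }
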