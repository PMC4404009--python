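"""Randomisation statistics for polygonal trait distributions.

- t-ratio polygonality: area of the data's convex hull over the area of
  the fitted enclosing triangle (1 = perfectly polygonal), with a
  column-permutation null,
- triangle similarity: intersection-over-union area of two triangles, with
  a null of random triangles drawn uniformly on a rectangle,
- diameter enrichment: equal-count distance bins from an archetype, a line
  fitted through bin means, and a value-permutation null for its slope.

All p-values are Monte-Carlo estimates reported with the 1/n_null floor
(never exactly zero).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from shapely.geometry import Polygon

from .archetype_fit import Polytope, fit_simplex

__all__ = [
    "TestResult",
    "EnrichmentResult",
    "t_ratio",
    "polygonality_test",
    "triangle_similarity",
    "similarity_test",
    "enrichment_by_distance",
]


@dataclass(frozen=True)
class TestResult:
    """A statistic, its Monte-Carlo null summary and p-value."""

    statistic: float
    p_value: float
    n_null: int
    seed: int | None
    null_mean: float
    null_sd: float
    null_quantiles: dict = field(default_factory=dict)
    note: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value outside [0, 1]")


@dataclass(frozen=True)
class EnrichmentResult:
    """Distance-binned value enrichment toward an archetype."""

    bin_edges: np.ndarray
    bin_means: np.ndarray
    slope: float
    p_value: float
    direction: str                 # "positive" | "negative" | "none"
    n_perm: int
    seed: int | None


def _hull_area(points: np.ndarray) -> float:
    try:
        return float(ConvexHull(points).volume)   # 2-D: .volume is the area
    except QhullError:
        return 0.0                                # collinear/degenerate data


def t_ratio(points: np.ndarray, simplex: Polytope) -> float:
    """Convex-hull area of the data over the area of the fitted triangle.

    Equals 1 for perfectly polygonal data (hull = triangle) and lies in
    (0, 1] whenever the triangle encloses the data; degenerate (collinear)
    data give 0.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[1] != 2 or len(pts) < 3:
        raise ValueError("t_ratio needs n >= 3 points in 2-D")
    tri_area = simplex.volume()
    if tri_area <= 1e-12:
        raise ValueError("zero-area simplex")
    return _hull_area(pts) / tri_area


def polygonality_test(
    points: np.ndarray,
    n_null: int = 10_000,
    seed: int | None = 0,
    refit_null: bool = True,
    fit_kwargs: dict | None = None,
) -> TestResult:
    """Randomisation test of how triangular a 2-D point cloud is.

    The statistic is the t-ratio of the data under its fitted enclosing
    triangle.  Each null replicate permutes every trait column
    independently (preserving the marginals exactly), refits the triangle
    (``refit_null=True``, conservative; set False to reuse the data's
    triangle) and recomputes the t-ratio.  p = fraction of null replicates
    with a larger t-ratio.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if len(pts) < 10:
        raise ValueError("need n >= 10 points")
    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    fit_kwargs = dict(fit_kwargs or {})
    fit_kwargs.setdefault("restarts", 1)
    rng = np.random.default_rng(seed)

    fit = fit_simplex(pts, seed=int(rng.integers(2**31 - 1)), **fit_kwargs)
    stat = t_ratio(pts, fit.polytope)

    null = np.empty(n_null)
    failures = 0
    for i in range(n_null):
        perm = np.column_stack([rng.permutation(col) for col in pts.T])
        try:
            if refit_null:
                f = fit_simplex(perm, seed=int(rng.integers(2**31 - 1)), **fit_kwargs)
                null[i] = t_ratio(perm, f.polytope)
            else:
                null[i] = t_ratio(perm, fit.polytope)
        except (ValueError, QhullError):
            null[i] = np.nan
            failures += 1
    ok = null[np.isfinite(null)]
    if len(ok) == 0:
        raise RuntimeError("all null replicates failed")
    p = max(float(np.mean(ok > stat)), 1.0 / len(ok))
    return TestResult(
        statistic=stat, p_value=p, n_null=len(ok), seed=seed,
        null_mean=float(ok.mean()), null_sd=float(ok.std()),
        null_quantiles={q: float(np.quantile(ok, q)) for q in (0.5, 0.95, 0.99)},
        note=f"{failures} failed replicates excluded" if failures else "",
    )


def _as_triangle(poly: Polytope) -> Polygon:
    if poly.dim != 2 or poly.k != 3:
        raise ValueError("expected a triangle (3 vertices in 2-D)")
    tri = Polygon(poly.vertices)
    if tri.area <= 1e-12:
        raise ValueError("degenerate triangle")
    return tri


def triangle_similarity(A: Polytope, B: Polytope) -> float:
    """Intersection area over union area of two triangles, in [0, 1].

    1 for identical triangles, 0 for disjoint ones; computed by exact
    polygon clipping.  Invariant under a common affine scaling.
    """
    ta, tb = _as_triangle(A), _as_triangle(B)
    inter = ta.intersection(tb).area
    union = ta.union(tb).area
    return float(inter / union)


def similarity_test(
    observed_ratio: float, n_null: int = 10_000, seed: int | None = 0
) -> TestResult:
    """How unusual an intersection/union ratio is among random triangles.

    The null draws pairs of triangles whose six vertices are i.i.d.
    uniform on the unit square (the ratio's distribution is independent of
    the rectangle chosen, being scale-equivariant in each axis);
    p = fraction of pairs with ratio >= observed, floored at 1/n_null.
    """
    if not 0.0 <= observed_ratio <= 1.0:
        raise ValueError("observed_ratio must be in [0, 1]")
    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    rng = np.random.default_rng(seed)
    null = np.empty(n_null)
    i = 0
    while i < n_null:
        v = rng.random((2, 3, 2))
        ta, tb = Polygon(v[0]), Polygon(v[1])
        if ta.area <= 1e-12 or tb.area <= 1e-12:
            continue                      # degenerate draw, redraw
        null[i] = ta.intersection(tb).area / ta.union(tb).area
        i += 1
    p = max(float(np.mean(null >= observed_ratio)), 1.0 / n_null)
    return TestResult(
        statistic=float(observed_ratio), p_value=p, n_null=n_null, seed=seed,
        null_mean=float(null.mean()), null_sd=float(null.std()),
        null_quantiles={q: float(np.quantile(null, q)) for q in (0.5, 0.99, 0.9999)},
    )


def enrichment_by_distance(
    points: np.ndarray,
    values: np.ndarray,
    vertex: np.ndarray,
    n_bins: int = 10,
    n_perm: int = 10_000,
    seed: int | None = 0,
    alpha: float = 0.05,
) -> EnrichmentResult:
    """Trend of a per-genus value with distance from an archetype.

    Distances are Euclidean in standardised trait space (each trait scaled
    by the data's standard deviation).  Genera are split into ``n_bins``
    equal-count bins by distance (ties broken by stable sort on index),
    the mean value per bin is taken, and a least-squares line is fitted
    through (bin index, bin mean).  The p-value permutes the values over
    genera and recomputes the slope (two-sided).
    """
    X = np.atleast_2d(np.asarray(points, dtype=float))
    y = np.asarray(values, dtype=float)
    v = np.asarray(vertex, dtype=float)
    n = len(X)
    if len(y) != n:
        raise ValueError("points and values length mismatch")
    if not 2 <= n_bins <= n:
        raise ValueError("need 2 <= n_bins <= n")
    if np.any(y <= 0):
        raise ValueError("values must be positive")
    sd = X.std(axis=0)
    sd = np.where(sd <= 0, 1.0, sd)
    dist = np.linalg.norm((X - v) / sd, axis=1)
    order = np.argsort(dist, kind="stable")
    bins = np.array_split(order, n_bins)      # counts differ by <= 1
    edges = np.array([dist[b[0]] for b in bins] + [dist[order[-1]]])
    idx = np.arange(n_bins, dtype=float)
    xc = idx - idx.mean()
    denom = float(np.sum(xc**2))

    def slope_of(vals: np.ndarray) -> float:
        means = np.array([vals[b].mean() for b in bins])
        return float(np.sum(xc * means) / denom)

    slope = slope_of(y)
    if np.ptp(y) == 0:
        return EnrichmentResult(edges, np.array([y[b].mean() for b in bins]),
                                0.0, 1.0, "none", 0, seed)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        null[i] = slope_of(y[rng.permutation(n)])
    p = max(float(np.mean(np.abs(null) >= abs(slope))), 1.0 / n_perm)
    direction = "none" if p > alpha else ("positive" if slope > 0 else "negative")
    return EnrichmentResult(
        bin_edges=edges,
        bin_means=np.array([y[b].mean() for b in bins]),
        slope=slope, p_value=p, direction=direction, n_perm=n_perm, seed=seed,
    )
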