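"""Performance functions over Raup morphospace, grid evaluation and argmax.

Three putative tasks are implemented as :class:`PerformanceSurface` objects
(higher value = better performance):

- :func:`economy_performance`: internal volume relative to shell material
  (cheap, buoyancy-friendly shells),
- :func:`growth_performance`: rate of diameter increase per unit of shell
  material produced (reciprocal of the penalty
  ``P = W / (Ratio(D, W) log W (1 + sqrt W))``),
- :func:`drag_performance`: hydrodynamic efficiency; measured drag tables
  can be interpolated, and the default is a documented monotone stand-in
  (drag increases with D, W and S, so the optimum is the low corner).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.interpolate import LinearNDInterpolator, NearestNDInterpolator
from scipy.optimize import minimize

from .shell_geometry import DEFAULT_THICKNESS_FRACTION, volume_ratio_many

__all__ = [
    "PerformanceSurface",
    "GridSpec",
    "economy_performance",
    "growth_performance",
    "drag_performance",
    "argmax_on_grid",
    "ArgmaxResult",
    "DEFAULT_GRID_2D",
    "DEFAULT_GRID_3D",
    "GROWTH_GRID",
]

TRAITS = ("D", "S", "W")


@dataclass(frozen=True)
class PerformanceSurface:
    """A scalar performance over (D, S, W) morphospace; higher is better."""

    name: str
    evaluator: Callable[[np.ndarray, np.ndarray, np.ndarray], np.ndarray]
    domain: dict = field(
        default_factory=lambda: {"D": (0.0, 0.95), "S": (0.1, 3.5), "W": (1.0 + 1e-6, 6.0)}
    )

    def __call__(self, D, S, W) -> np.ndarray:
        D, S, W = np.broadcast_arrays(
            np.atleast_1d(np.asarray(D, float)), np.asarray(S, float), np.asarray(W, float)
        )
        return np.asarray(self.evaluator(D, S, W), dtype=float)


@dataclass(frozen=True)
class GridSpec:
    """Rectangular evaluation grid over the traits.

    ``axes`` maps trait name -> (min, max, n_points); traits absent from
    ``axes`` must appear in ``fixed`` (e.g. ``fixed={"S": 1.0}`` for the
    classic two-dimensional W-D analyses).
    """

    axes: dict
    fixed: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, (lo, hi, n) in self.axes.items():
            if name not in TRAITS:
                raise ValueError(f"unknown trait {name!r}")
            if not (lo < hi and n >= 2):
                raise ValueError(f"bad axis {name}: ({lo}, {hi}, {n})")
        missing = set(TRAITS) - set(self.axes) - set(self.fixed)
        if missing:
            raise ValueError(f"traits neither gridded nor fixed: {sorted(missing)}")

    @property
    def active(self) -> tuple[str, ...]:
        return tuple(t for t in TRAITS if t in self.axes)

    def coordinates(self) -> dict:
        return {n: np.linspace(lo, hi, n_pts) for n, (lo, hi, n_pts) in self.axes.items()}

    def points(self) -> pd.DataFrame:
        """All grid points as a DataFrame with D, S, W columns."""
        coords = self.coordinates()
        mesh = np.meshgrid(*(coords[t] for t in self.active), indexing="ij")
        df = pd.DataFrame({t: m.ravel() for t, m in zip(self.active, mesh)})
        for t in TRAITS:
            if t not in df:
                df[t] = float(self.fixed[t])
        return df[list(TRAITS)]


#: Default grids; W starts just above the W = 1 singular limit.
DEFAULT_GRID_2D = GridSpec(
    axes={"D": (0.0, 0.95, 101), "W": (1.0 + 1e-6, 5.0, 101)}, fixed={"S": 1.0}
)
DEFAULT_GRID_3D = GridSpec(
    axes={"D": (0.0, 0.95, 101), "S": (0.1, 3.5, 36), "W": (1.0 + 1e-6, 5.0, 101)}
)
GROWTH_GRID = GridSpec(
    axes={"D": (0.0, 0.95, 101), "W": (1.0 + 1e-6, 6.0, 101)}, fixed={"S": 1.0}
)


def economy_performance(
    thickness_fraction: float = DEFAULT_THICKNESS_FRACTION, **conventions
) -> PerformanceSurface:
    """Shell economy: internal volume relative to shell-material volume."""

    def ev(D, S, W):
        return volume_ratio_many(D, S, W, thickness_fraction, **conventions)

    return PerformanceSurface(name="economy", evaluator=ev)


def growth_performance(
    S_eval: float = 1.0,
    thickness_fraction: float = DEFAULT_THICKNESS_FRACTION,
    **conventions,
) -> PerformanceSurface:
    """Rapid-growth performance, the reciprocal of the diameter penalty.

    The penalty ``P = W / (Ratio(D, W) log W (1 + sqrt W))`` accumulates the
    reciprocal shell diameter over growth (small shells are exposed to
    predation longer); ``Ratio`` is the internal-to-shell volume ratio
    evaluated at ``S = S_eval``.  Performance is ``1/P``, which vanishes as
    ``W -> 1`` (the penalty diverges with ``1 / log W``) and peaks at
    evolute, rapidly expanding shells.
    """

    def ev(D, S, W):
        if np.any(W <= 1.0):
            raise ValueError("growth performance requires W > 1")
        ratio = volume_ratio_many(D, S_eval, W, thickness_fraction, **conventions)
        return ratio * np.log(W) * (1.0 + np.sqrt(W)) / W

    return PerformanceSurface(name="growth", evaluator=ev)


def drag_performance(
    table: pd.DataFrame | None = None,
    coefficients: tuple[float, float, float] = (1.0, 0.5, 1.0),
) -> PerformanceSurface:
    """Hydrodynamic performance (higher = lower drag).

    Without a table, a documented monotone stand-in is used:
    ``-(alpha D + beta S + gamma W)`` with positive ``coefficients``
    ``(alpha, beta, gamma)``, so performance strictly decreases in each
    trait and the argmax on any box is its low corner.  This encodes the
    only facts used downstream: drag grows monotonically with D and W, and
    the hydrodynamic optimum has low S.

    With a table (columns D, S, W, cd), negated drag coefficients are
    linearly interpolated inside the convex hull of the measurements and
    nearest-neighbour extrapolated outside.
    """
    if table is None:
        alpha, beta, gamma = coefficients
        if min(alpha, beta, gamma) <= 0:
            raise ValueError("stand-in coefficients must be positive")

        def ev(D, S, W):
            return -(alpha * D + beta * S + gamma * W)

        return PerformanceSurface(name="drag", evaluator=ev)

    required = {"D", "S", "W", "cd"}
    if not required.issubset(table.columns):
        raise ValueError(f"drag table needs columns {sorted(required)}")
    pts = table[["D", "S", "W"]].to_numpy(float)
    if len(np.unique(pts, axis=0)) != len(pts):
        raise ValueError("drag table has duplicate (D, S, W) coordinates")
    values = -table["cd"].to_numpy(float)
    lin = LinearNDInterpolator(pts, values)
    near = NearestNDInterpolator(pts, values)

    def ev(D, S, W):
        q = np.column_stack([np.ravel(D), np.ravel(S), np.ravel(W)])
        v = lin(q)
        bad = np.isnan(v)
        if bad.any():
            v[bad] = near(q[bad])
        return v.reshape(np.shape(D))

    return PerformanceSurface(name="drag", evaluator=ev)


@dataclass(frozen=True)
class ArgmaxResult:
    point: dict          # trait -> coordinate of the maximiser
    value: float
    refined: bool
    on_boundary: tuple[str, ...]   # traits whose maximiser sits on a grid edge


def argmax_on_grid(
    surface: PerformanceSurface, grid: GridSpec, refine: bool = True
) -> ArgmaxResult:
    """Deterministic grid argmax, optionally refined by local optimisation.

    Ties are broken toward the lexicographically smallest (D, S, W) (grids
    enumerate points in that order, and the first maximum wins).  The
    refinement is a Nelder-Mead polish clipped to the grid's bounding box;
    maximisers on the box edge are reported in ``on_boundary``.
    """
    pts = grid.points()
    vals = surface(pts["D"].to_numpy(), pts["S"].to_numpy(), pts["W"].to_numpy())
    if np.all(np.isnan(vals)):
        raise ValueError("surface is NaN on the whole grid")
    i = int(np.nanargmax(vals))
    best = {t: float(pts.iloc[i][t]) for t in TRAITS}
    best_val = float(vals[i])
    refined = False

    lo = {t: grid.axes[t][0] for t in grid.active}
    hi = {t: grid.axes[t][1] for t in grid.active}
    if refine:
        active = grid.active

        def neg(x):
            p = dict(best)
            for t, xi in zip(active, x):
                p[t] = float(np.clip(xi, lo[t], hi[t]))
            return -float(surface(p["D"], p["S"], p["W"])[0])

        x0 = np.array([best[t] for t in active])
        res = minimize(neg, x0, method="Nelder-Mead",
                       options={"xatol": 1e-5, "fatol": 1e-12, "maxiter": 400})
        if np.isfinite(res.fun) and -res.fun >= best_val:
            for t, xi in zip(active, res.x):
                best[t] = float(np.clip(xi, lo[t], hi[t]))
            best_val = float(-res.fun)
            refined = True

    tol = {t: 1e-9 + 1e-4 * (hi[t] - lo[t]) for t in grid.active}
    boundary = tuple(
        t for t in grid.active
        if best[t] <= lo[t] + tol[t] or best[t] >= hi[t] - tol[t]
    )
    return ArgmaxResult(point=best, value=best_val, refined=refined, on_boundary=boundary)
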