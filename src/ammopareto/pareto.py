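"""Pareto front (non-dominated set) of performance surfaces on a trait grid.

A phenotype is on the Pareto front if no other phenotype is at least as
good at every task and strictly better at one.  With a single task only
the maxima survive; with several tasks the front fills a region whose
extreme points are the single-task optima (the archetypes).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .performance import GridSpec, PerformanceSurface, argmax_on_grid

__all__ = ["FrontResult", "non_dominated", "front_on_grid"]


@dataclass(frozen=True)
class FrontResult:
    """Grid points, their performance vectors and the non-dominated mask."""

    points: pd.DataFrame            # columns D, S, W
    performances: np.ndarray        # (n_points, n_tasks)
    mask: np.ndarray                # boolean, True = on the front
    archetypes: pd.DataFrame        # one row per task: argmax point + value

    @property
    def front(self) -> pd.DataFrame:
        out = self.points.copy()
        out["on_front"] = self.mask
        return out


def non_dominated(performance_vectors: np.ndarray) -> np.ndarray:
    """Boolean mask of Pareto-non-dominated rows.

    Row i is kept iff no row j has all performances >= and at least one >.
    Ties are kept (two identical vectors both survive).  Deterministic;
    O(n^2) in blocks, fine for grids up to ~1e5 points with few tasks.
    """
    P = np.asarray(performance_vectors, dtype=float)
    if P.ndim == 1:
        P = P[:, None]
    if P.size == 0:
        raise ValueError("empty performance input")
    if not np.all(np.isfinite(P)):
        raise ValueError("performance vectors must be finite")
    n = len(P)
    # sorting by total performance: a dominator always has a strictly larger
    # sum, so only earlier rows in this order can dominate
    order = np.argsort(-P.sum(axis=1), kind="stable")
    Ps = P[order]
    keep = np.ones(n, dtype=bool)
    block = max(1, int(2e7) // max(n, 1))
    for start in range(0, n, block):
        stop = min(start + block, n)
        cand = Ps[start:stop]                       # (m, k)
        ge = np.all(Ps[None, :, :] >= cand[:, None, :], axis=2)
        gt = np.any(Ps[None, :, :] > cand[:, None, :], axis=2)
        keep[start:stop] = ~np.any(ge & gt, axis=1)
    out = np.empty(n, dtype=bool)
    out[order] = keep
    return out


def front_on_grid(
    surfaces: list[PerformanceSurface], grid: GridSpec, refine_archetypes: bool = True
) -> FrontResult:
    """Evaluate the surfaces on the grid and keep the non-dominated points.

    Also reports each task's single-task argmax (the archetype); these
    always belong to the front.
    """
    if len(surfaces) < 2:
        raise ValueError("need at least two performance surfaces")
    names = [s.name for s in surfaces]
    if len(set(names)) != len(names):
        raise ValueError("surface names must be unique")
    pts = grid.points()
    D, S, W = (pts[t].to_numpy() for t in ("D", "S", "W"))
    P = np.column_stack([s(D, S, W) for s in surfaces])
    mask = non_dominated(P)
    rows = []
    for s in surfaces:
        am = argmax_on_grid(s, grid, refine=refine_archetypes)
        rows.append({"task": s.name, **am.point, "value": am.value})
    arch = pd.DataFrame(rows)
    return FrontResult(points=pts, performances=P, mask=mask, archetypes=arch)
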