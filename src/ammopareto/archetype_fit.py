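"""Enclosing-polytope and archetype fits for trait data.

Two fitting strategies:

- :func:`fit_simplex`: minimum-volume simplex that (softly) encloses the
  data — the classic approach for triangles in two-trait planes.  The
  objective is ``simplex volume + outside_penalty * sum of hinge distances
  of points outside``, optimised deterministically from a convex-hull-based
  initial simplex.
- :func:`fit_pcha`: principal convex hull / archetypal analysis for
  general k-vertex polytopes (k need not be d+1): archetypes are
  (optionally relaxed) convex combinations of data points, and each data
  point is reconstructed as a convex combination of archetypes; the
  Frobenius reconstruction error is minimised by alternating projected
  gradient with multi-restart.

Traits are standardised to zero mean and unit variance before fitting
(their natural ranges differ by an order of magnitude) and the fitted
vertices are mapped back; reported RMS errors are in standardised
("normalised") units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.spatial import ConvexHull, QhullError

__all__ = [
    "Polytope",
    "FitReport",
    "fit_simplex",
    "fit_pcha",
    "rms_profile",
    "project",
    "simplex_margins",
]


@dataclass(frozen=True)
class Polytope:
    """k ordered vertices in d-dimensional trait space."""

    vertices: np.ndarray           # (k, d)
    kind: str = "general"          # "simplex" | "general"
    trait_names: tuple = ()

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or not np.all(np.isfinite(v)):
            raise ValueError("vertices must be a finite (k, d) array")
        object.__setattr__(self, "vertices", v)
        if self.kind == "simplex" and len(v) != v.shape[1] + 1:
            raise ValueError("a simplex in d dimensions has d + 1 vertices")

    @property
    def k(self) -> int:
        return len(self.vertices)

    @property
    def dim(self) -> int:
        return self.vertices.shape[1]

    def volume(self) -> float:
        """Area (d=2) or volume (d=3) of the convex hull of the vertices."""
        if self.kind == "simplex":
            diffs = self.vertices[1:] - self.vertices[0]
            from math import factorial

            return abs(np.linalg.det(diffs)) / factorial(self.dim)
        hull = ConvexHull(self.vertices)
        return float(hull.volume)

    def contains(self, points: np.ndarray, tol: float = 1e-9) -> np.ndarray:
        """Boolean membership in the convex hull of the vertices.

        Solved as a least-squares convex-combination test per point.
        """
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        w = barycentric_weights(pts, self.vertices, n_iter=2000)
        recon = w @ self.vertices
        scale = max(1.0, float(np.abs(self.vertices).max()))
        return np.linalg.norm(recon - pts, axis=1) <= tol * scale + 1e-12


@dataclass(frozen=True)
class FitReport:
    """Result of an enclosing-polytope fit."""

    polytope: Polytope
    rms_error: float               # standardised units
    fraction_inside: float
    iterations: int
    converged: bool
    seed: int | None
    restart_seeds: tuple = ()
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.rms_error < 0 or not 0.0 <= self.fraction_inside <= 1.0:
            raise ValueError("invalid fit report")


# ---------------------------------------------------------------------------
# shared helpers


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    if np.any(sd <= 0):
        raise ValueError("degenerate data: a trait has zero variance")
    return (X - mu) / sd, mu, sd


def _simplex_project_columns(Y: np.ndarray) -> np.ndarray:
    """Euclidean projection of each column of Y onto the probability simplex."""
    k, n = Y.shape
    U = np.sort(Y, axis=0)[::-1]
    css = np.cumsum(U, axis=0) - 1.0
    ind = np.arange(1, k + 1)[:, None]
    cond = U - css / ind > 0
    rho = k - 1 - np.argmax(cond[::-1], axis=0)
    theta = css[rho, np.arange(n)] / (rho + 1.0)
    return np.maximum(Y - theta, 0.0)


def barycentric_weights(points: np.ndarray, vertices: np.ndarray,
                        n_iter: int = 1000) -> np.ndarray:
    """Least-squares convex-combination weights of points over vertices.

    Accelerated (FISTA) projected gradient on ``min ||P - w V||`` with w on
    the probability simplex; deterministic.  Returns (n_points, k) weights.
    """
    P = np.atleast_2d(np.asarray(points, dtype=float))
    V = np.asarray(vertices, dtype=float)
    k = len(V)
    W = np.full((len(P), k), 1.0 / k)
    Y = W.copy()
    t = 1.0
    G = V @ V.T
    lip = max(np.linalg.eigvalsh(G).max(), 1e-12)
    PVt = P @ V.T
    for _ in range(n_iter):
        grad = Y @ G - PVt
        W_new = _simplex_project_columns((Y - grad / lip).T).T
        t_new = (1.0 + np.sqrt(1.0 + 4.0 * t * t)) / 2.0
        Y = W_new + ((t - 1.0) / t_new) * (W_new - W)
        W, t = W_new, t_new
    return W


def simplex_margins(points: np.ndarray, vertices: np.ndarray) -> np.ndarray:
    """Outward signed distance of points to each facet of a simplex.

    Positive entries mean the point lies outside that facet's plane; the
    maximum over facets is zero/negative exactly for interior points and a
    lower bound on the Euclidean distance outside (a hinge margin).
    Shape: (n_points, k_facets).
    """
    V = np.asarray(vertices, dtype=float)
    P = np.atleast_2d(np.asarray(points, dtype=float))
    k, d = V.shape
    margins = np.empty((len(P), k))
    for i in range(k):
        face = np.delete(V, i, axis=0)
        opp = V[i]
        if d == 2:
            e = face[1] - face[0]
            normal = np.array([e[1], -e[0]])
        else:
            normal = np.cross(face[1] - face[0], face[2] - face[0])
        nn = np.linalg.norm(normal)
        if nn < 1e-300:
            raise ValueError("degenerate simplex facet")
        normal = normal / nn
        if np.dot(opp - face[0], normal) > 0:   # orient outward
            normal = -normal
        margins[:, i] = (P - face[0]) @ normal
    return margins


def _initial_simplex(Z: np.ndarray, expand: float = 1.10) -> np.ndarray:
    """Deterministic initial simplex from the convex hull of the data.

    Picks the hull-vertex simplex of maximal volume (exhaustive over hull
    vertices, which are few) and inflates it about its centroid.
    """
    from itertools import combinations
    from math import factorial

    d = Z.shape[1]
    try:
        hull_pts = Z[ConvexHull(Z).vertices]
    except QhullError as exc:
        raise ValueError(
            "degenerate data: points are collinear/coplanar, no "
            f"full-dimensional simplex exists ({exc.args[0].splitlines()[0]})"
        ) from None
    if len(hull_pts) > 24:        # keep the exhaustive search tiny
        order = np.argsort(-np.linalg.norm(hull_pts - hull_pts.mean(0), axis=1))
        hull_pts = hull_pts[order[:24]]
    best, best_vol = None, -1.0
    for idx in combinations(range(len(hull_pts)), d + 1):
        V = hull_pts[list(idx)]
        vol = abs(np.linalg.det(V[1:] - V[0])) / factorial(d)
        if vol > best_vol:
            best, best_vol = V, vol
    centroid = best.mean(axis=0)
    return centroid + expand * (best - centroid)


def fit_simplex(
    points: np.ndarray,
    outside_penalty: float = 200.0,
    standardize: bool = True,
    restarts: int = 4,
    seed: int | None = 0,
    maxiter: int = 4000,
    trait_names: tuple = (),
) -> FitReport:
    """Minimum-volume softly-enclosing simplex (k = d + 1 vertices).

    Minimises ``volume + outside_penalty * sum_i max(0, margin_i)`` where
    ``margin_i`` is the hinge distance of point i outside the simplex,
    starting from an inflated maximal-volume hull simplex; additional
    restarts jitter the initialisation with a seeded RNG (seeds recorded).
    """
    X = np.atleast_2d(np.asarray(points, dtype=float))
    n, d = X.shape
    if d not in (2, 3):
        raise ValueError("fit_simplex supports 2- or 3-dimensional traits")
    if n <= d + 1:
        raise ValueError("need more points than simplex vertices")
    if standardize:
        Z, mu, sd = _standardize(X)
    else:
        Z, mu, sd = X, np.zeros(d), np.ones(d)
    from math import factorial

    def objective(flat: np.ndarray) -> float:
        V = flat.reshape(d + 1, d)
        vol = abs(np.linalg.det(V[1:] - V[0])) / factorial(d)
        if vol < 1e-12:
            return 1e6
        m = simplex_margins(Z, V)
        hinge = np.clip(m.max(axis=1), 0.0, None).sum()
        return vol + outside_penalty * hinge

    V0 = _initial_simplex(Z)
    rng = np.random.default_rng(seed)
    restart_seeds = tuple(
        int(s) for s in rng.integers(0, 2**31 - 1, size=max(restarts, 1))
    )
    best_flat, best_obj, total_iter = None, np.inf, 0
    for r, rs in enumerate(restart_seeds):
        jitter = 0.0 if r == 0 else 0.1 * np.random.default_rng(rs).standard_normal(V0.shape)
        res = minimize(
            objective, (V0 + jitter).ravel(), method="Nelder-Mead",
            options={"xatol": 1e-7, "fatol": 1e-10, "maxiter": maxiter,
                     "maxfev": int(1.5 * maxiter)},
        )
        total_iter += res.nit
        if res.fun < best_obj:
            best_obj, best_flat = res.fun, res.x
            converged = bool(res.success)
    Vz = best_flat.reshape(d + 1, d)
    margins = np.clip(simplex_margins(Z, Vz).max(axis=1), 0.0, None)
    poly = Polytope(vertices=Vz * sd + mu, kind="simplex", trait_names=trait_names)
    return FitReport(
        polytope=poly,
        rms_error=float(np.sqrt(np.mean(margins**2))),
        fraction_inside=float(np.mean(margins <= 1e-9)),
        iterations=total_iter,
        converged=converged,
        seed=seed,
        restart_seeds=restart_seeds,
        extra={"objective": float(best_obj), "standardized": standardize,
               "mean": mu.tolist(), "scale": sd.tolist()},
    )


# ---------------------------------------------------------------------------
# PCHA


def _furthest_sum(Z: np.ndarray, k: int, start: int) -> list[int]:
    """FurthestSum seeding: iteratively add the point with the largest
    summed distance to the points chosen so far, then drop the seed."""
    chosen = [int(start)]
    dist_sum = np.zeros(len(Z))
    for _ in range(k):
        dist_sum += np.linalg.norm(Z - Z[chosen[-1]], axis=1)
        d = dist_sum.copy()
        d[chosen] = -1.0
        chosen.append(int(np.argmax(d)))
    return chosen[1 : k + 1]


def _pcha_once(Z, k, delta, rng, max_iter, tol, furthest: bool = False,
               init_C=None, init_S=None):
    """One PCHA run: block alternating projected gradient on C and S.

    Z: (n, d) standardised data.  Model: Z ~ S^T (C^T Z) with C (n, k)
    columns on the (delta-relaxed) simplex and S (k, n) columns on the
    simplex.  Each outer iteration runs several inner gradient steps per
    block with adaptive backtracking step sizes; ``furthest`` seeds the
    archetypes at FurthestSum extreme points instead of random data rows.
    Returns (sse, archetypes (k, d), S, iterations, converged).
    """
    X = Z.T                                   # (d, n)
    n = X.shape[1]
    if init_C is not None:
        C = np.array(init_C, dtype=float)
    else:
        if furthest:
            init = np.array(_furthest_sum(Z, k, int(rng.integers(n))))
        else:
            init = rng.choice(n, size=k, replace=False)
        C = np.zeros((n, k))
        C[init, np.arange(k)] = 1.0
    S = np.full((k, n), 1.0 / k) if init_S is None else np.array(init_S, dtype=float)

    def sse(C, S):
        R = X - (X @ C) @ S
        return float(np.sum(R * R))

    def project_C(C):
        if delta == 0:
            return _simplex_project_columns(C)
        C = np.maximum(C, 0.0)
        s = C.sum(axis=0, keepdims=True)
        s = np.where(s < 1e-12, 1.0, s)
        return C * (np.clip(s, 1.0 - delta, 1.0 + delta) / s)

    err = sse(C, S)
    mu_s, mu_c = 1.0, 1.0
    inner = 8
    it = 0
    converged = False
    for it in range(1, max_iter + 1):
        err_start = err
        # --- S block (projected gradient, fixed archetypes)
        A = X @ C
        AtA, AtX = A.T @ A, A.T @ X
        for _ in range(inner):
            G = AtA @ S - AtX
            for _ in range(18):
                S_new = _simplex_project_columns(S - mu_s * G)
                e = sse(C, S_new)
                if e <= err:
                    S, err = S_new, e
                    mu_s *= 1.5
                    break
                mu_s /= 2.0
        # --- C block (projected gradient, fixed weights)
        SSt, XSt = S @ S.T, X @ S.T
        for _ in range(inner):
            G_C = Z @ ((X @ C) @ SSt - XSt)
            for _ in range(18):
                C_new = project_C(C - mu_c * G_C)
                e = sse(C_new, S)
                if e <= err:
                    C, err = C_new, e
                    mu_c *= 1.5
                    break
                mu_c /= 2.0
        if (err_start - err) / max(err_start, 1e-300) < tol and it > 3:
            converged = True
            break
    return err, (X @ C).T, S, C, it, converged


def fit_pcha(
    points: np.ndarray,
    k: int,
    delta: float = 0.0,
    restarts: int = 20,
    seed: int | None = 0,
    max_iter: int = 500,
    tol: float = 1e-8,
    standardize: bool = True,
    trait_names: tuple = (),
    extra_inits: tuple = (),
) -> FitReport:
    """Principal-convex-hull (archetypal) analysis with k archetypes.

    Archetypes are constrained to (delta-relaxed) convex combinations of
    the data, data points are reconstructed as convex combinations of the
    archetypes, and the Frobenius reconstruction error is minimised by
    alternating projected gradient.  ``restarts`` seeded restarts are run
    (seeds = spawned from ``seed``, recorded in the report) and the best
    solution is returned.  Non-convergence is flagged, best iterate kept.
    """
    X = np.atleast_2d(np.asarray(points, dtype=float))
    n, d = X.shape
    if not 2 <= k <= n:
        raise ValueError(f"need 2 <= k <= n, got k={k}, n={n}")
    if delta < 0:
        raise ValueError("delta must be >= 0")
    if standardize:
        Z, mu, sd = _standardize(X)
    else:
        Z, mu, sd = X, np.zeros(d), np.ones(d)
    rng = np.random.default_rng(seed)
    restart_seeds = tuple(int(s) for s in rng.integers(0, 2**31 - 1, size=max(restarts, 1)))
    best = None
    for i, rs in enumerate(restart_seeds):
        out = _pcha_once(Z, k, delta, np.random.default_rng(rs), max_iter, tol,
                         furthest=(i == 0))
        if best is None or out[0] < best[0]:
            best = out
    for C0, S0 in extra_inits:
        out = _pcha_once(Z, k, delta, np.random.default_rng(restart_seeds[0]),
                         max_iter, tol, init_C=C0, init_S=S0)
        if out[0] < best[0]:
            best = out
    err, arch_z, S, C, iters, converged = best
    recon = (arch_z.T @ S).T
    resid = np.linalg.norm(Z - recon, axis=1)
    inside = Polytope(arch_z, kind="general").contains(Z, tol=1e-6)
    return FitReport(
        polytope=Polytope(arch_z * sd + mu, kind="general", trait_names=trait_names),
        rms_error=float(np.sqrt(np.mean(resid**2))),
        fraction_inside=float(np.mean(inside | (resid <= 1e-6))),
        iterations=iters,
        converged=converged,
        seed=seed,
        restart_seeds=restart_seeds,
        extra={"sse": float(err), "S": S, "C": C,
               "standardized": standardize, "mean": mu.tolist(), "scale": sd.tolist()},
    )


def rms_profile(
    points: np.ndarray,
    k_range=range(2, 9),
    restarts: int = 10,
    seed: int | None = 0,
    **kwargs,
) -> dict[int, float]:
    """PCHA RMS reconstruction error for each vertex count k.

    Shares the restart budget and base seed across k so the profile is
    comparable; non-increasing in k up to solver tolerance.  The elbow of
    this profile indicates the parsimonious number of archetypes.
    """
    X = np.atleast_2d(np.asarray(points, dtype=float))
    out: dict[int, float] = {}
    prev: FitReport | None = None
    for k in sorted(int(k) for k in k_range):
        inits = ()
        if prev is not None and prev.polytope.k == k - 1:
            # nested warm start: previous solution plus a point-mass archetype
            # on the worst-reconstructed row; makes the profile structurally
            # non-increasing (the k-model contains the k-1 solution)
            S_prev = prev.extra["S"]
            resid = np.linalg.norm(
                (X - X.mean(0)) / X.std(0)
                - S_prev.T @ ((prev.polytope.vertices - X.mean(0)) / X.std(0)),
                axis=1,
            )
            newcol = np.zeros((len(X), 1))
            newcol[int(np.argmax(resid)), 0] = 1.0
            inits = ((np.hstack([prev.extra["C"], newcol]),
                      np.vstack([S_prev, np.zeros((1, len(X)))])),)
        rep = fit_pcha(points, k, restarts=restarts, seed=seed,
                       extra_inits=inits, **kwargs)
        out[k] = rep.rms_error
        prev = rep
    return out


def project(
    polytope: Polytope, axes: tuple[int, ...] | list[int], merge_tol: float = 0.08
) -> tuple[Polytope, dict[int, int]]:
    """Project a polytope onto a subset of trait axes.

    Drops the other coordinates and greedily merges projected vertices
    closer than ``merge_tol`` (in the projected space, after scaling each
    axis by the vertex coordinate range) into their mean.  Returns the
    projected polytope and a map original-vertex-index -> merged-vertex
    index.
    """
    axes = tuple(int(a) for a in axes)
    if any(a < 0 or a >= polytope.dim for a in axes) or len(set(axes)) != len(axes):
        raise ValueError(f"invalid axes {axes} for dimension {polytope.dim}")
    V = polytope.vertices[:, axes]
    span = np.ptp(V, axis=0)
    span = np.where(span <= 0, 1.0, span)
    Vn = V / span
    merge_map: dict[int, int] = {}
    groups: list[list[int]] = []
    for i, v in enumerate(Vn):
        for gi, g in enumerate(groups):
            if np.linalg.norm(Vn[g].mean(axis=0) - v) < merge_tol:
                g.append(i)
                merge_map[i] = gi
                break
        else:
            groups.append([i])
            merge_map[i] = len(groups) - 1
    merged = np.array([V[g].mean(axis=0) for g in groups])
    names = tuple(polytope.trait_names[a] for a in axes) if polytope.trait_names else ()
    return Polytope(merged, kind="general", trait_names=names), merge_map
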