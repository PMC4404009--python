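"""Geometry of the Raup logarithmic-spiral shell.

A planispiral shell is described by three dimensionless parameters
(Raup's classic morphospace):

``W``
    whorl expansion rate: the factor by which the spiral radius grows per
    full revolution, ``r(theta) = W**(theta / 2 pi)``.
``D``
    ratio of the inner to the outer radius of the aperture (umbilical
    exposure), ``0 <= D < 1``.
``S``
    aperture shape: width over height of the generating ellipse; ``S < 1``
    gives compressed (oblate-opening) shells, ``S > 1`` depressed ones.

All quantities produced here are dimensionless ratios, expressed in units
of the outer spiral radius at the aperture; the shell is self-similar, so
every per-angle integrand scales as a pure power of the radius and ratios
of integrands are position independent.

Aperture convention: in the half-plane at spiral angle ``theta`` the
aperture is an ellipse spanning the radial interval ``[D, 1]``, i.e. with
center ``c = (1 + D)/2``, radial semi-axis ``a = (1 - D)/2`` and axial
(width) semi-axis ``b = S * a``.

Whorl overlap: when ``W < 1/D`` the aperture interpenetrates the whorl laid
down one revolution earlier (the shell is involute); beyond that curve
successive whorls do not touch (gyroconic shells).  Where the new section
abuts previously built whorls the wall is shared, which changes the
shell-material budget; several conventions for that correction are
implemented (see :func:`volume_ratio`).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "ShellModel",
    "WhorlSection",
    "spiral_radius",
    "diameter_factor",
    "whorl_overlap",
    "whorl_section",
    "volume_ratio",
    "volume_ratio_many",
    "surface_to_volume",
    "DEFAULT_THICKNESS_FRACTION",
]

#: Shell wall thickness as a fraction of the local whorl-section radius
#: (geometric mean of the section semi-axes).  Empirical value for
#: normally-coiled ammonoids.
DEFAULT_THICKNESS_FRACTION = 0.077

# Gauss-Legendre rule shared by all section integrals.  256 nodes give
# ~1e-12 accuracy on the smooth ellipse-arc integrands; the exposed/shared
# wall split introduces an O(1/n) edge error, well below the model
# uncertainty of the overlap conventions.
_NQUAD = 256
_GL_X, _GL_W = np.polynomial.legendre.leggauss(_NQUAD)

# Whorls more than _KMAX revolutions back are handled by the continuous
# scale envelope (relevant only as W -> 1, where discrete scales are dense).
_KMAX = 40

# W = 1 is a closed-circle singular limit; overlap geometry is evaluated at
# W >= 1 + _W_EPS and optimisation grids should start above 1.
_W_EPS = 1e-9


@dataclass(frozen=True)
class ShellModel:
    """A logarithmic-spiral shell in Raup's (D, W, S) morphospace.

    Parameters
    ----------
    D : float
        Inner-to-outer aperture radius ratio, in ``[0, 1)``.
    W : float
        Whorl expansion rate per revolution, ``>= 1`` (``W = 1`` only as a
        degenerate limit).
    S : float
        Aperture width/height ratio, ``> 0``.
    thickness_fraction : float
        Shell wall thickness divided by the local whorl-section radius.
    """

    D: float
    W: float
    S: float = 1.0
    thickness_fraction: float = DEFAULT_THICKNESS_FRACTION

    def __post_init__(self) -> None:
        if not 0.0 <= self.D < 1.0:
            raise ValueError(f"D must be in [0, 1), got {self.D}")
        if not self.W >= 1.0:
            raise ValueError(f"W must be >= 1, got {self.W}")
        if not self.S > 0.0:
            raise ValueError(f"S must be > 0, got {self.S}")
        if not self.thickness_fraction > 0.0:
            raise ValueError(
                f"thickness_fraction must be > 0, got {self.thickness_fraction}"
            )

    def with_(self, **kwargs) -> "ShellModel":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)

    @property
    def section_semi_axes(self) -> tuple[float, float, float]:
        """(center, radial semi-axis, axial semi-axis) of the aperture."""
        a = (1.0 - self.D) / 2.0
        return (1.0 + self.D) / 2.0, a, self.S * a


@dataclass(frozen=True)
class WhorlSection:
    """Cross-section of one whorl at outer radius 1.

    ``exposed_perimeter`` is the part of the ellipse circumference not
    lying against previously built whorls; it equals ``total_perimeter``
    for gyroconic (non-overlapping) shells.
    """

    area: float
    total_perimeter: float
    exposed_perimeter: float

    def __post_init__(self) -> None:
        if not self.area > 0:
            raise ValueError("degenerate section: area must be > 0")
        if not 0 < self.exposed_perimeter <= self.total_perimeter * (1 + 1e-12):
            raise ValueError("exposed_perimeter must be in (0, total_perimeter]")


# ---------------------------------------------------------------------------
# simple closed forms


def spiral_radius(shell: ShellModel, theta) -> np.ndarray | float:
    """Spiral radius at angle ``theta`` (radians), in units of r(0).

    ``r(theta) = W**(theta / 2 pi)``: one full revolution multiplies the
    radius by W.
    """
    return shell.W ** (np.asarray(theta) / (2.0 * np.pi))


def diameter_factor(shell: ShellModel) -> float:
    """Shell diameter across the coiling axis, in units of the outer radius.

    The diameter at angle ``theta`` spans the aperture and the half-whorl
    opposite it: ``diam = r(theta) + r(theta - pi) = r (1 + W**-0.5)``; the
    returned factor is ``1 + W**-0.5`` (2 for a circle, decreasing in W).
    """
    return 1.0 + shell.W ** -0.5


def whorl_overlap(shell: ShellModel) -> tuple[bool, float]:
    """Whether the whorl interpenetrates the previous one, and how deeply.

    Overlap occurs iff ``W < 1/D`` (previous whorl's outer radius ``1/W``
    exceeds the new inner radius ``D``).  The depth ``max(0, 1/W - D)`` is
    in units of the current outer radius.
    """
    depth = max(0.0, 1.0 / shell.W - shell.D)
    return depth > 0.0, depth


# ---------------------------------------------------------------------------
# overlap geometry kernels (vectorised over points; quadrature axis last)


def _ellipse_halfheight(rho, c, a, b):
    """Half-height |y| of the ellipse boundary at radial coordinate rho."""
    u = (rho - c) / a
    return np.where(np.abs(u) < 1.0, b * np.sqrt(np.clip(1.0 - u * u, 0.0, None)), 0.0)


def _covered_halfheight(rho, D, c, a, b, W, cover):
    """Half-height of the already-built region at radial coordinate rho.

    ``cover`` selects the model of what counts as previously built:

    - ``"sections"``: the union of the whorl sections laid down 1, 2, ...
      revolutions earlier (each the aperture ellipse scaled by ``W**-k``),
      with a continuous-scale envelope for whorls deeper than the explicit
      union (the envelope is the tangent cone ``|y| <= b rho / sqrt(D)``
      restricted to scales actually reached).
    - ``"circle"``: everything within distance ``1/W`` of the coiling
      center (the construction suggested by treating the previous whorl's
      outer surface as a sphere).
    - ``"halfplane"``: everything at radial coordinate below ``1/W``.
    - ``"none"``: nothing (gyroconic accounting everywhere).
    """
    if cover == "none":
        return np.zeros_like(rho)
    if cover == "halfplane":
        return np.where(rho < 1.0 / W, np.inf, 0.0)
    if cover == "circle":
        return np.sqrt(np.maximum(0.0, W ** -2.0 - rho ** 2))
    if cover == "sections":
        s = 1.0 / W
        Y = _ellipse_halfheight(rho, c * s, a * s, b * s)
        for k in range(2, _KMAX + 1):
            s = W ** (-float(k))
            # deeper whorls lie entirely below the section's inner edge
            if np.all(s < np.minimum(D, 1e-3)):
                break
            Y = np.maximum(Y, _ellipse_halfheight(rho, c * s, a * s, b * s))
        slim = W ** (-float(_KMAX))
        with np.errstate(divide="ignore", invalid="ignore"):
            cone = np.where(
                (D > 0) & (c * rho / np.maximum(D, 1e-300) <= slim),
                b * rho / np.sqrt(np.maximum(D, 1e-300)),
                0.0,
            )
        return np.maximum(Y, cone)
    raise ValueError(f"unknown cover model: {cover!r}")


def _section_integrals(D, S, W, cover):
    """Per-angle integrands of one whorl section, vectorised over points.

    Returns a dict with, all in outer-radius units:

    - ``area``: full section area, and ``area_swept`` = radial first moment
      (area weighted by distance from the coiling axis, i.e. the
      solid-of-revolution volume integrand per radian),
    - ``net_area_swept``: same moment restricted to the part of the section
      not lying inside previously built whorls,
    - ``perimeter``: full circumference,
    - ``exposed_swept`` / ``shared_swept``: radial-moment arc integrals of
      the exposed and shared parts of the circumference,
    - ``exposed_len`` / ``shared_len``: their unweighted arc lengths.
    """
    D = np.atleast_1d(np.asarray(D, dtype=float))
    S = np.broadcast_to(np.asarray(S, dtype=float), D.shape)
    W = np.broadcast_to(np.asarray(W, dtype=float), D.shape)
    W = np.maximum(W, 1.0 + _W_EPS)
    a = ((1.0 - D) / 2.0)[:, None]
    b = (S * (1.0 - D) / 2.0)[:, None]
    c = ((1.0 + D) / 2.0)[:, None]
    Dc, Wc = D[:, None], W[:, None]

    # area integrals over the radial band rho in [D, 1]
    rho = Dc + (1.0 - Dc) * (_GL_X + 1.0) / 2.0
    wr = (1.0 - Dc) / 2.0 * _GL_W
    Yn = _ellipse_halfheight(rho, c, a, b)
    Yc = np.minimum(_covered_halfheight(rho, Dc, c, a, b, Wc, cover), Yn)
    area = 2.0 * np.sum(wr * Yn, axis=1)
    area_swept = 2.0 * np.sum(wr * rho * Yn, axis=1)
    net_area_swept = 2.0 * np.sum(wr * rho * (Yn - Yc), axis=1)

    # arc integrals over the ellipse boundary, phi in [0, pi] (x2 symmetry)
    phi = np.pi * (_GL_X + 1.0) / 2.0
    wp = np.pi / 2.0 * _GL_W
    rp = c + a * np.cos(phi)
    yp = b * np.sin(phi)
    ds = np.sqrt(a ** 2 * np.sin(phi) ** 2 + b ** 2 * np.cos(phi) ** 2)
    exposed = yp >= _covered_halfheight(rp, Dc, c, a, b, Wc, cover)
    perimeter = 2.0 * np.sum(wp * ds, axis=1)
    exposed_swept = 2.0 * np.sum(np.where(exposed, wp * rp * ds, 0.0), axis=1)
    shared_swept = 2.0 * np.sum(np.where(exposed, 0.0, wp * rp * ds), axis=1)
    exposed_len = 2.0 * np.sum(np.where(exposed, wp * ds, 0.0), axis=1)
    shared_len = 2.0 * np.sum(np.where(exposed, 0.0, wp * ds), axis=1)
    return {
        "a": a[:, 0], "b": b[:, 0], "c": c[:, 0],
        "area": area, "area_swept": area_swept,
        "net_area_swept": net_area_swept,
        "perimeter": perimeter,
        "exposed_swept": exposed_swept, "shared_swept": shared_swept,
        "exposed_len": exposed_len, "shared_len": shared_len,
    }


# ---------------------------------------------------------------------------
# public section / volume functions


def whorl_section(shell: ShellModel, cover: str = "sections") -> WhorlSection:
    """Aperture cross-section at outer radius 1.

    The section is an ellipse of radial height ``1 - D`` and width
    ``S (1 - D)``; ``exposed_perimeter`` excludes the arc lying inside
    previously built whorls (see :func:`_covered_halfheight` for the cover
    models).
    """
    if shell.D >= 1.0 - 1e-9:
        raise ValueError("degenerate aperture: D too close to 1")
    g = _section_integrals(shell.D, shell.S, shell.W, cover)
    exposed = float(g["exposed_len"][0])
    total = float(g["perimeter"][0])
    return WhorlSection(
        area=float(g["area"][0]),
        total_perimeter=total,
        exposed_perimeter=min(exposed, total) if exposed > 0 else total * 1e-12,
    )


def volume_ratio_many(
    D,
    S,
    W,
    thickness_fraction: float = DEFAULT_THICKNESS_FRACTION,
    *,
    cover: str = "sections",
    internal_area: str = "full",
    shared_wall_weight: float = 0.5,
) -> np.ndarray:
    """Internal-volume to shell-material-volume ratio, vectorised.

    Both volumes are per-angle integrands of the self-similar spiral
    (solids of revolution about the coiling axis), so their ratio is
    independent of position along the spiral and of overall scale:

    - internal volume per radian = radial first moment of the aperture
      section (``internal_area="full"``, default: the whole tube counts,
      chambers plus body) or of the part of the section outside previously
      built whorls (``internal_area="net"``),
    - shell-material volume per radian = wall thickness x radial-moment arc
      integral of the wall being built.  Thickness is
      ``thickness_fraction x sqrt(a b)`` (local whorl-section scale; this
      is what makes the ratio constant on the gyroconic region at fixed S).
      Walls shared with a previous whorl are charged ``shared_wall_weight``
      of their cost (default 0.5: a shared wall serves two whorls).

    Parameters are broadcast against each other; returns an array.
    """
    if not 0.0 <= shared_wall_weight <= 1.0:
        raise ValueError("shared_wall_weight must be in [0, 1]")
    if internal_area not in ("full", "net"):
        raise ValueError(f"internal_area must be 'full' or 'net', got {internal_area!r}")
    D, S, W = np.broadcast_arrays(
        np.atleast_1d(np.asarray(D, dtype=float)),
        np.asarray(S, dtype=float),
        np.asarray(W, dtype=float),
    )
    if np.any(D >= 1.0) or np.any(D < 0.0):
        raise ValueError("D must be in [0, 1)")
    out = np.empty(D.shape, dtype=float)
    chunk = 2048   # keep the (points x quadrature) workspace cache-friendly
    flatD, flatS, flatW = D.ravel(), S.ravel(), W.ravel()
    flat_out = out.reshape(-1)
    for start in range(0, flatD.size, chunk):
        sl = slice(start, start + chunk)
        g = _section_integrals(flatD[sl], flatS[sl], flatW[sl], cover)
        vol = g["area_swept"] if internal_area == "full" else g["net_area_swept"]
        wall = g["exposed_swept"] + shared_wall_weight * g["shared_swept"]
        material = thickness_fraction * np.sqrt(g["a"] * g["b"]) * wall
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.where(material > 0, vol / np.maximum(material, 1e-300), np.inf)
        flat_out[sl] = np.where(vol <= 0, 0.0, r)
    return out


def volume_ratio(shell: ShellModel, **conventions) -> float:
    """Internal volume / shell-material volume for one shell.

    See :func:`volume_ratio_many` for the construction and the convention
    keywords (``cover``, ``internal_area``, ``shared_wall_weight``).
    """
    return float(
        volume_ratio_many(
            shell.D, shell.S, shell.W, shell.thickness_fraction, **conventions
        )[0]
    )


def surface_to_volume(
    shell: ShellModel,
    *,
    normalized: bool = True,
    cover: str = "sections",
) -> float:
    """Exposed outer surface area relative to internal volume.

    Uses the same per-angle integrand construction as :func:`volume_ratio`:
    surface per radian = radial-moment arc integral of the exposed wall,
    volume per radian = radial first moment of the section.

    With ``normalized=True`` (default) the compactness index
    ``surface / volume**(1/2)`` is returned (both per-radian integrands in
    outer-radius units); it is symmetric under S <-> 1/S and minimised by
    the most globular shapes — at fixed D and W it is minimal at S = 1.
    With ``normalized=False`` the raw ratio per unit outer radius is
    returned (note this raw ratio trivially falls as the section area
    grows with S, so globularity comparisons should use the normalised
    form).
    """
    if shell.D >= 1.0 - 1e-9:
        raise ValueError("degenerate aperture: D too close to 1")
    g = _section_integrals(shell.D, shell.S, shell.W, cover)
    surf = float(g["exposed_swept"][0])
    vol = float(g["area_swept"][0])
    if vol <= 0:
        raise ValueError("degenerate shell: zero internal volume")
    return surf / vol ** 0.5 if normalized else surf / vol
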