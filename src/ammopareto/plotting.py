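"""Minimal figure helpers (matplotlib, headless-safe).

All analysis results are plain numbers; these helpers only render the two
diagnostic views used most often: the (D, W) morphospace with fitted
triangles and gyroconic boundary, and the PCHA error-versus-k profile.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .archetype_fit import Polytope

__all__ = ["plot_morphospace", "plot_rms_profile"]


def plot_morphospace(points, triangle: Polytope | None = None, ax=None,
                     label: str | None = None):
    """Scatter genera in the (D, W) plane with the W = 1/D coiling boundary."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    ax.scatter(pts[:, 0], pts[:, 1], s=8, alpha=0.5, label=label)
    D = np.linspace(0.12, 1.0, 200)
    ax.plot(D, 1.0 / D, "g--", lw=1, label="W = 1/D")
    if triangle is not None:
        V = np.vstack([triangle.vertices, triangle.vertices[:1]])
        ax.plot(V[:, 0], V[:, 1], "k-", lw=1.5)
    ax.set_xlabel("D (umbilical ratio)")
    ax.set_ylabel("W (whorl expansion)")
    ax.set_xlim(-0.05, 1.0)
    if label:
        ax.legend(frameon=False)
    return ax


def plot_rms_profile(profile: dict[int, float], ax=None):
    """PCHA reconstruction error against the number of archetypes."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    ks = sorted(profile)
    ax.plot(ks, [profile[k] for k in ks], "o-")
    ax.set_xlabel("number of archetypes k")
    ax.set_ylabel("RMS error (standardised)")
    ax.set_xticks(ks)
    return ax
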