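"""Biplot display of a fitted log-ratio PCA.

Form biplot: pairs at their principal coordinates F_p, genotype-pair
categories as arrows at the standard coordinates G_s (optionally rescaled
for legibility); reference relationships drawn as convex hulls.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .composition import PART_LABELS
from .lrpca import LrPcaFit

__all__ = ["biplot"]


def biplot(
    fit: LrPcaFit,
    labels: Sequence[str] | None = None,
    supplementary: np.ndarray | None = None,
    dims: tuple[int, int] = (0, 1),
    loading_scale: float | None = None,
    hulls: bool = True,
    ax=None,
):
    """Draw a two-dimensional biplot of the fit.

    ``labels`` groups the training scores (one convex hull and colour per
    group); ``supplementary`` adds projected coordinates as open dots.
    ``loading_scale`` rescales the loading arrows for display only (defaults
    to fitting them inside the score cloud).
    """
    import matplotlib.pyplot as plt
    from scipy.spatial import ConvexHull

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    i, j = dims
    F = fit.scores[:, [i, j]]
    G = fit.loadings[:, [i, j]]
    if loading_scale is None:
        span = np.abs(F).max() or 1.0
        loading_scale = 0.8 * span / (np.abs(G).max() or 1.0)
    if labels is None:
        ax.scatter(F[:, 0], F[:, 1], s=8, alpha=0.6)
    else:
        labels = np.asarray(labels)
        for lab in dict.fromkeys(labels):  # preserves first-seen order
            pts = F[labels == lab]
            sc = ax.scatter(pts[:, 0], pts[:, 1], s=8, alpha=0.6, label=lab)
            if hulls and len(pts) >= 3:
                hull = ConvexHull(pts)
                closed = np.append(hull.vertices, hull.vertices[0])
                ax.plot(pts[closed, 0], pts[closed, 1], lw=1, color=sc.get_facecolor()[0])
        ax.legend(fontsize=8)
    if supplementary is not None:
        S = np.atleast_2d(supplementary)[:, [i, j]]
        ax.scatter(S[:, 0], S[:, 1], s=14, facecolors="none", edgecolors="k", lw=0.6)
    for part, (gx, gy) in zip(PART_LABELS, G * loading_scale):
        ax.annotate(
            part,
            xy=(gx, gy),
            xytext=(0, 0),
            textcoords="data",
            arrowprops=dict(arrowstyle="<-", lw=0.8, color="gray"),
            fontsize=8,
            color="gray",
        )
    evr = fit.explained_variance_ratio()
    ax.set_xlabel(f"PC{i + 1} ({100 * evr[i]:.1f}%)")
    ax.set_ylabel(f"PC{j + 1} ({100 * evr[j]:.1f}%)")
    ax.axhline(0, lw=0.3, color="gray")
    ax.axvline(0, lw=0.3, color="gray")
    return ax
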