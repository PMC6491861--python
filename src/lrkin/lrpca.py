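"""Centered log-ratio principal component analysis of compositions.

The clr transform maps a strictly positive D-part composition x to
ln(x_i / gm(x)), a zero-sum vector; information in a composition lives in the
ratios of its parts and the clr respects that (it is scale invariant).  A
log-ratio PCA double-centers the clr-transformed data matrix (rows and
columns) and takes its SVD,  X_cclr = U D V' = F_p G_s',  with principal
biplot coordinates F_p = U D for the compositions (pairs of individuals) and
standard coordinates G_s = V for the parts (genotype-pair categories).  For
six-part genotype-sharing compositions the clr constraint leaves at most five
informative dimensions.

Supplementary compositions are placed on a fitted biplot by regression:
center their clr rows with the *training* column means and project onto the
orthonormal loadings, which for training rows reproduces their own scores
exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["ClrVector", "LrPcaFit", "SupplementaryScores", "clr", "fit_lrpca", "project_supplementary"]


@dataclass
class ClrVector:
    """clr-transformed composition with its geometric mean."""

    values: np.ndarray
    geometric_mean: float


@dataclass
class LrPcaFit:
    """A fitted log-ratio PCA.

    ``clr_column_means`` are the column means of the row-centered log data
    (needed to center supplementary material), ``loadings`` the D x r
    orthonormal standard coordinates G_s, ``scores`` the n x r principal
    coordinates F_p = U D, and ``singular_values`` the non-increasing
    singular values.
    """

    clr_column_means: np.ndarray
    loadings: np.ndarray
    singular_values: np.ndarray
    scores: np.ndarray
    D: int
    n: int

    @property
    def rank(self) -> int:
        return len(self.singular_values)

    def explained_variance_ratio(self) -> np.ndarray:
        ss = self.singular_values**2
        return ss / ss.sum() if ss.sum() > 0 else ss


@dataclass
class SupplementaryScores:
    """Biplot coordinates of supplementary compositions."""

    coords: np.ndarray  # m x r
    pair_ids: list[tuple[str, str]] | None = None


def _clr_rows(X: np.ndarray) -> np.ndarray:
    if (X <= 0).any():
        raise ValueError(
            "compositions must be strictly positive; apply a zero_policy "
            "(see close_composition) before the log-ratio transform"
        )
    L = np.log(X)
    return L - L.mean(axis=-1, keepdims=True)


def clr(x: np.ndarray) -> ClrVector:
    """Centered log-ratio transform of one composition.

    clr(x)_i = ln(x_i / gm(x)); the result sums to zero and is invariant to
    rescaling of x.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("clr expects a single composition; use fit_lrpca for matrices")
    values = _clr_rows(x[None, :])[0]
    gm = float(np.exp(np.mean(np.log(x))))
    return ClrVector(values=values, geometric_mean=gm)


def fit_lrpca(X: np.ndarray, rank_tol: float = 1e-10) -> LrPcaFit:
    """Fit a log-ratio PCA to a matrix of compositions (rows).

    Rows are clr-transformed (row-centered logs), the matrix is then
    column-centered, and the SVD taken.  Components with singular value below
    ``rank_tol`` times the largest are dropped (the clr constraint guarantees
    at least one null dimension).  Loading signs are fixed so each column's
    largest-magnitude entry is positive.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least two compositions")
    Xclr = _clr_rows(X)
    col_means = Xclr.mean(axis=0)
    Xcclr = Xclr - col_means
    U, s, Vt = np.linalg.svd(Xcclr, full_matrices=False)
    if s[0] <= 0:
        warnings.warn("degenerate input: all compositions identical; rank-0 fit")
        keep = np.zeros(0, dtype=bool)
    else:
        keep = s > rank_tol * s[0]
    U, s, V = U[:, keep], s[keep], Vt[keep].T
    # SVD sign ambiguity: make the largest-magnitude entry of each loading
    # column positive so fits are reproducible.
    for j in range(V.shape[1]):
        i = np.argmax(np.abs(V[:, j]))
        if V[i, j] < 0:
            V[:, j] = -V[:, j]
            U[:, j] = -U[:, j]
    return LrPcaFit(
        clr_column_means=col_means,
        loadings=V,
        singular_values=s,
        scores=U * s,
        D=X.shape[1],
        n=X.shape[0],
    )


def project_supplementary(
    Y: np.ndarray,
    fit: LrPcaFit,
    pair_ids: list[tuple[str, str]] | None = None,
) -> SupplementaryScores:
    """Project supplementary compositions onto a fitted biplot.

    The supplementary rows are clr-transformed, centered with the training
    clr column means, and regressed on the loadings; with orthonormal G_s the
    regression reduces to the projection Y_cclr G_s.  Projecting a training
    composition reproduces its own score row.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape[1] != fit.D:
        raise ValueError(f"compositions have {Y.shape[1]} parts; fit expects {fit.D}")
    Ycclr = _clr_rows(Y) - fit.clr_column_means
    coords = Ycclr @ fit.loadings
    return SupplementaryScores(coords=coords, pair_ids=pair_ids)
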