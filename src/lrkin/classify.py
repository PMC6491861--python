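"""Relationship classification, structural-zero filtering and unrelated-subset
selection.

Classification is Gaussian linear discriminant analysis with a pooled
within-class covariance and equal priors, trained on the principal-component
scores of simulated reference pairs; empirical pairs are assigned the class
with the highest posterior probability, with ties broken toward the lower
(more related) degree.  MZ and PO pairs carry structural zeros in the
genotype-pair counts (k20 = 0 for PO; additionally k10 = k21 = 0 for MZ) and
are removed beforehand by a simple count filter rather than classified.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .pedigree import DEGREE_OF

__all__ = [
    "ClassifierModel",
    "ClassificationReport",
    "StructuralZeroPartition",
    "lda_fit",
    "classify_pairs",
    "structural_zero_filter",
    "unrelated_subset",
]


def _degree_key(label: str) -> tuple[float, str]:
    return (DEGREE_OF.get(label, float("inf")), label)


@dataclass
class ClassifierModel:
    """Equal-prior LDA on d-dimensional score space.

    ``labels`` are ordered by increasing degree of relationship so that an
    argmax over posterior columns breaks exact ties toward the more related
    class.
    """

    labels: tuple[str, ...]
    means: np.ndarray  # n_classes x d
    pooled_cov: np.ndarray  # d x d
    priors: np.ndarray
    d: int
    _lda: LinearDiscriminantAnalysis = field(repr=False, default=None)

    def posteriors(self, scores: np.ndarray) -> np.ndarray:
        scores = np.atleast_2d(np.asarray(scores, dtype=float))
        if scores.shape[1] != self.d:
            raise ValueError(f"scores have {scores.shape[1]} columns; model uses d={self.d}")
        post = self._lda.predict_proba(scores)
        order = [list(self._lda.classes_).index(lab) for lab in self.labels]
        return post[:, order]


@dataclass
class ClassificationReport:
    """Predicted labels, posteriors and (when truth is known) accuracy."""

    predicted: np.ndarray
    posteriors: pd.DataFrame  # columns = class labels in degree order
    confusion: pd.DataFrame | None = None  # rows true, columns predicted
    class_rates: pd.Series | None = None
    overall_rate: float | None = None


def lda_fit(scores: np.ndarray, labels: Sequence[str]) -> ClassifierModel:
    """Fit the equal-prior linear discriminant on training scores.

    Requires at least two classes and, per class, more members than the score
    dimension; a (numerically) singular pooled covariance raises with a hint
    to use fewer components.
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    labels = np.asarray(labels, dtype=str)
    if scores.shape[0] != len(labels):
        raise ValueError("scores and labels length mismatch")
    classes = sorted(set(labels), key=_degree_key)
    d = scores.shape[1]
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    for c in classes:
        if (labels == c).sum() < d + 1:
            raise ValueError(f"class {c!r} has fewer than d+1={d + 1} members")
    # Pooled within-class covariance; verified positive definite so the
    # discriminant is well defined.
    resid = np.vstack([scores[labels == c] - scores[labels == c].mean(axis=0) for c in classes])
    pooled = resid.T @ resid / (len(labels) - len(classes))
    try:
        np.linalg.cholesky(pooled)
    except np.linalg.LinAlgError:
        raise np.linalg.LinAlgError(
            "pooled within-class covariance is singular; use fewer components"
        ) from None
    priors = np.full(len(classes), 1.0 / len(classes))
    est = LinearDiscriminantAnalysis(solver="svd", priors=priors, store_covariance=True)
    est.fit(scores, labels)
    means = np.vstack([scores[labels == c].mean(axis=0) for c in classes])
    return ClassifierModel(
        labels=tuple(classes), means=means, pooled_cov=pooled, priors=priors, d=d, _lda=est
    )


def classify_pairs(
    model: ClassifierModel,
    scores: np.ndarray,
    pair_ids: Sequence[tuple[str, str]] | None = None,
    true_labels: Sequence[str] | None = None,
) -> ClassificationReport:
    """Assign each pair the maximum-posterior relationship.

    When ``true_labels`` are supplied (simulation experiments) the confusion
    matrix and per-class/overall classification rates are included.
    """
    post = model.posteriors(scores)
    pred_idx = post.argmax(axis=1)  # first index wins ties -> lower degree
    predicted = np.array([model.labels[i] for i in pred_idx])
    index = pd.MultiIndex.from_tuples(pair_ids, names=["pair_i", "pair_j"]) if pair_ids else None
    post_df = pd.DataFrame(post, columns=list(model.labels), index=index)
    confusion = class_rates = overall = None
    if true_labels is not None:
        true = np.asarray(true_labels, dtype=str)
        classes = sorted(set(true) | set(model.labels), key=_degree_key)
        confusion = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
        for t, p in zip(true, predicted):
            confusion.loc[t, p] += 1
        present = [c for c in classes if confusion.loc[c].sum() > 0]
        class_rates = pd.Series(
            {c: confusion.loc[c, c] / confusion.loc[c].sum() for c in present}
        )
        overall = float((predicted == true).mean())
    return ClassificationReport(
        predicted=predicted,
        posteriors=post_df,
        confusion=confusion,
        class_rates=class_rates,
        overall_rate=overall,
    )


@dataclass
class StructuralZeroPartition:
    """Outcome of the k20/k structural-zero screen."""

    po_index: np.ndarray
    mz_index: np.ndarray
    remainder_index: np.ndarray
    flags: np.ndarray  # per-row "PO" / "MZ" / "" strings


def structural_zero_filter(
    counts: np.ndarray, threshold: float = 0.005
) -> StructuralZeroPartition:
    """Flag PO/MZ candidates by their (near-)structural zeros.

    Pairs with k20/k below ``threshold`` are flagged; flagged pairs whose
    heterozygote-sharing fraction (k10 + k21)/k is also below the threshold
    are labelled MZ, the rest PO.  Operates on raw (pre-closure) counts.
    """
    c = np.atleast_2d(np.asarray(counts, dtype=float))
    k = c.sum(axis=1)
    if (k <= 0).any():
        raise ValueError("empty pair in counts")
    flagged = c[:, 2] / k < threshold
    mz = flagged & ((c[:, 1] + c[:, 4]) / k < threshold)
    po = flagged & ~mz
    flags = np.where(mz, "MZ", np.where(po, "PO", ""))
    idx = np.arange(len(k))
    return StructuralZeroPartition(
        po_index=idx[po], mz_index=idx[mz], remainder_index=idx[~flagged], flags=flags
    )


def unrelated_subset(
    phi: pd.DataFrame | np.ndarray,
    n_individuals: int | None = None,
    threshold: float = 0.05,
) -> list[int]:
    """Select an approximately unrelated set of individuals.

    ``phi`` is either the tidy frame from :func:`lrkin.ibd.pairwise_king`
    (columns ``i``, ``j``, ``phi``) or an array of [i, j, phi] rows.  The
    co-ancestry coefficient of a pair is 2*phi; individuals are greedily
    removed — always the one involved in the most pairs whose co-ancestry
    exceeds ``threshold``, ties to the lower index — until no such pair
    remains.  Returns the retained individual indices, sorted.
    """
    if isinstance(phi, pd.DataFrame):
        tab = phi[["i", "j", "phi"]].to_numpy()
    else:
        tab = np.asarray(phi, dtype=float)
    ii = tab[:, 0].astype(int)
    jj = tab[:, 1].astype(int)
    theta = 2.0 * tab[:, 2]
    if n_individuals is None:
        n_individuals = int(max(ii.max(), jj.max())) + 1
    hot = theta > threshold
    alive = np.ones(n_individuals, dtype=bool)
    while True:
        active = hot & alive[ii] & alive[jj]
        if not active.any():
            break
        viol = np.bincount(ii[active], minlength=n_individuals) + np.bincount(
            jj[active], minlength=n_individuals
        )
        viol[~alive] = 0
        alive[int(np.argmax(viol))] = False  # argmax ties -> lower index
    kept = [int(i) for i in np.flatnonzero(alive)]
    if not kept:
        raise ValueError("no individuals retained: population too related for the threshold")
    return kept
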