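"""Simulation experiments: classification studies, method comparison, and the
iterative peel-and-zoom exploration.

The central design simulates, under HWE at a stated MAF, 100 independent
gene-dropped pairs of each relationship in a training set and an equally
sized held-out test set; log-ratio PCA is fitted on the training
compositions, test pairs are projected, and LDA on the leading d principal
components yields per-class and overall classification rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .classify import ClassificationReport, classify_pairs, lda_fit
from .composition import ibs_summary
from .ibd import king_from_counts, mom_from_counts
from .lrpca import LrPcaFit, fit_lrpca, project_supplementary
from .pedigree import HweFounders, ReferencePairSet, build_reference_set

__all__ = [
    "ExperimentResult",
    "classification_experiment",
    "compare_methods",
    "PeelIteration",
    "peel_and_zoom",
]

#: The remote-relationship panel of the main simulation study.
REMOTE_PANEL = ("FC", "4th", "5th", "6th", "UN")


@dataclass
class ExperimentResult:
    """Held-out classification rates of one simulated experiment."""

    overall_rates: dict[int, float]  # d -> overall rate
    class_rates: dict[int, pd.Series]
    confusions: dict[int, pd.DataFrame]
    fit: LrPcaFit
    train: ReferencePairSet
    test: ReferencePairSet
    reports: dict[int, ClassificationReport] = field(default_factory=dict)


def _scores_for(
    ref: ReferencePairSet, fit: LrPcaFit, zero_policy: str
) -> np.ndarray:
    return project_supplementary(ref.compositions(zero_policy), fit).coords


def classification_experiment(
    maf: float = 0.5,
    n_snps: int = 35_000,
    relationships: Sequence[str] = REMOTE_PANEL,
    n_pairs: int = 100,
    d_values: Sequence[int] = (1, 2, 3, 4, 5),
    seed: int = 0,
    zero_policy: str = "replace0.5",
    resubstitution: bool = False,
    keep_reports: bool = False,
) -> ExperimentResult:
    """Train/test classification study at one MAF and SNP count.

    Simulates independent training and test reference sets (held-out
    evaluation; set ``resubstitution=True`` to score the training set
    itself), fits log-ratio PCA on the training compositions and reports LDA
    rates for every requested number of components d.
    """
    ss = np.random.SeedSequence(seed)
    train_seed, test_seed = ss.spawn(2)
    founders = HweFounders(maf, n_snps)
    train = build_reference_set(relationships, founders, n_pairs, seed=train_seed)
    test = train if resubstitution else build_reference_set(
        relationships, founders, n_pairs, seed=test_seed
    )
    fit = fit_lrpca(train.compositions(zero_policy))
    train_scores = fit.scores
    test_scores = train_scores if resubstitution else _scores_for(test, fit, zero_policy)
    overall: dict[int, float] = {}
    class_rates: dict[int, pd.Series] = {}
    confusions: dict[int, pd.DataFrame] = {}
    reports: dict[int, ClassificationReport] = {}
    for d in d_values:
        if d > fit.rank:
            raise ValueError(f"d={d} exceeds the fitted rank {fit.rank}")
        model = lda_fit(train_scores[:, :d], train.labels)
        rep = classify_pairs(model, test_scores[:, :d], true_labels=test.labels)
        overall[d] = rep.overall_rate
        class_rates[d] = rep.class_rates
        confusions[d] = rep.confusion
        if keep_reports:
            reports[d] = rep
    return ExperimentResult(
        overall_rates=overall,
        class_rates=class_rates,
        confusions=confusions,
        fit=fit,
        train=train,
        test=test,
        reports=reports,
    )


def _feature_matrix(ref: ReferencePairSet, method: str, d: int, maf: float,
                    fit: LrPcaFit | None, zero_policy: str) -> np.ndarray:
    if method == "ms":
        feats = np.array(
            [(s.m, s.s) for s in (ibs_summary(c) for c in ref.counts)]
        )
    elif method == "p0p2":
        feats = np.array(
            [(s.p0, s.p2) for s in (ibs_summary(c) for c in ref.counts)]
        )
    elif method == "k0k1":
        ests = [mom_from_counts(c, maf) for c in ref.counts]
        feats = np.array([(e.k0, e.k1) for e in ests])
    elif method == "king":
        feats = np.array(
            [
                [king_from_counts(c, hi, hj)]
                for c, (hi, hj) in zip(ref.counts, ref.het_counts)
            ]
        )
    elif method == "lrpca":
        feats = _scores_for(ref, fit, zero_policy)[:, :d]
    else:
        raise ValueError(f"unknown method {method!r}")
    return feats


def compare_methods(
    maf: float = 0.5,
    n_snps: int = 5_000,
    relationships: Sequence[str] = REMOTE_PANEL,
    n_pairs: int = 100,
    n_replicates: int = 25,
    d: int = 3,
    methods: Sequence[str] = ("ms", "p0p2", "k0k1", "lrpca"),
    seed: int = 0,
    zero_policy: str = "replace0.5",
) -> pd.DataFrame:
    """Classification-rate comparison of lr-PCA against the classical plots.

    Every method sees the same simulated train/test pairs per replicate:
    ``ms`` = (m, s) features, ``p0p2`` = (p0, p2), ``k0k1`` = moment-estimated
    (k0, k1), ``lrpca`` = the leading d log-ratio principal components.
    Returns per-class and overall ("All") rates averaged over replicates,
    indexed by method.
    """
    ss = np.random.SeedSequence(seed)
    rows: list[pd.Series] = []
    founders = HweFounders(maf, n_snps)
    for rep_seed in ss.spawn(n_replicates):
        train_seed, test_seed = rep_seed.spawn(2)
        train = build_reference_set(relationships, founders, n_pairs, seed=train_seed)
        test = build_reference_set(relationships, founders, n_pairs, seed=test_seed)
        fit = fit_lrpca(train.compositions(zero_policy))
        d_use = min(d, fit.rank)
        for method in methods:
            tr = _feature_matrix(train, method, d_use, maf, fit, zero_policy)
            te = _feature_matrix(test, method, d_use, maf, fit, zero_policy)
            model = lda_fit(tr, train.labels)
            rep = classify_pairs(model, te, true_labels=test.labels)
            row = rep.class_rates.copy()
            row["All"] = rep.overall_rate
            row["method"] = method
            rows.append(row)
    out = pd.DataFrame(rows).groupby("method").mean()
    return out.loc[list(methods)]


@dataclass
class PeelIteration:
    """Record of one peel-and-zoom round."""

    reference_labels: tuple[str, ...]
    fit: LrPcaFit
    report: ClassificationReport
    kept_rows: np.ndarray  # indices (into the original composition matrix) still in play
    peeled_rows: np.ndarray
    peeled_predicted: np.ndarray  # predicted label of each peeled row
    peeled_labels: tuple[str, ...]


def peel_and_zoom(
    compositions: np.ndarray,
    reference_builder: Callable[[Sequence[str], np.random.SeedSequence], ReferencePairSet],
    relationships: Sequence[str],
    peel_schedule: Sequence[Sequence[str]],
    n_pcs: int = 3,
    seed: int = 0,
    zero_policy: str = "replace0.5",
) -> list[PeelIteration]:
    """Iteratively classify, remove, and refit.

    Each round builds a fresh reference set restricted to the relationships
    still under consideration (``reference_builder(labels, seed)``), fits
    log-ratio PCA on it, projects the surviving empirical compositions,
    classifies them with LDA, then removes the pairs assigned to that round's
    peel categories; the next round's reference set drops those relationships
    as well, zooming in on the remoter structure.  An empty peel schedule
    performs a single classification round with nothing removed.
    """
    comps = np.atleast_2d(np.asarray(compositions, dtype=float))
    ss = np.random.SeedSequence(seed)
    current = np.arange(comps.shape[0])
    labels = list(relationships)
    iterations: list[PeelIteration] = []
    schedule = [tuple(step) for step in peel_schedule] or [()]
    for step, step_seed in zip(schedule, ss.spawn(len(schedule))):
        if len(current) == 0:
            raise ValueError("no empirical pairs left to analyse")
        unknown = set(step) - set(labels)
        if unknown:
            raise ValueError(f"peel categories {sorted(unknown)} not in the reference set")
        ref = reference_builder(labels, step_seed)
        fit = fit_lrpca(ref.compositions(zero_policy))
        d = min(n_pcs, fit.rank)
        model = lda_fit(fit.scores[:, :d], ref.labels)
        coords = project_supplementary(comps[current], fit).coords[:, :d]
        report = classify_pairs(model, coords)
        peel_mask = np.isin(report.predicted, list(step))
        iterations.append(
            PeelIteration(
                reference_labels=tuple(labels),
                fit=fit,
                report=report,
                kept_rows=current[~peel_mask],
                peeled_rows=current[peel_mask],
                peeled_predicted=report.predicted[peel_mask],
                peeled_labels=tuple(step),
            )
        )
        current = current[~peel_mask]
        labels = [lab for lab in labels if lab not in step]
    return iterations
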