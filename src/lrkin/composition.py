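"""Genotype-pair compositions and IBS allele-sharing statistics.

For a pair of diploid individuals typed at bi-allelic variants (dosage coded
0 = AA, 1 = AB, 2 = BB for the B allele), every variant falls in one of six
unordered genotype-pair categories::

    k00 (AA,AA)   k10 (AA,AB)   k20 (AA,BB)
    k11 (AB,AB)   k21 (AB,BB)   k22 (BB,BB)

The vector of the six counts over the k jointly typed variants carries the
full identity-by-state information for the pair.  Dividing by k (closure)
yields a six-part composition that lives on the open five-dimensional
simplex; the classical IBS summaries (p0, p1, p2, mean m and standard
deviation s of the per-variant IBS allele count) are linear or quadratic
functions of it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MISSING",
    "PART_LABELS",
    "GenotypeMatrix",
    "PairComposition",
    "IbsSummary",
    "MissingGenotypeError",
    "EmptyPairError",
    "ibs_count",
    "genotype_pair_counts",
    "close_composition",
    "ibs_summary",
    "all_pair_compositions",
    "pair_table",
]

#: Sentinel for a missing dosage in integer genotype matrices.
MISSING = -1

#: Column labels of the six-part composition, in (k00,k10,k20,k11,k21,k22) order.
PART_LABELS = ("AA.AA", "AA.AB", "AA.BB", "AB.AB", "AB.BB", "BB.BB")

# Map an ordered dosage pair (a, b) to its unordered category index in the
# (k00, k10, k20, k11, k21, k22) layout.
_CODE = np.array(
    [
        [0, 1, 2],
        [1, 3, 4],
        [2, 4, 5],
    ],
    dtype=np.intp,
)

# IBS allele count for ordered dosage pair (a, b): 2 - |a - b|.
_IBS = np.array(
    [
        [2, 1, 0],
        [1, 2, 1],
        [0, 1, 2],
    ],
    dtype=np.intp,
)

#: Number of IBS alleles shared by each of the six categories, in layout order.
IBS_PER_CATEGORY = np.array([2, 1, 0, 2, 1, 2], dtype=np.intp)


class MissingGenotypeError(ValueError):
    """A dosage needed for an IBS computation is missing."""


class EmptyPairError(ValueError):
    """A pair of individuals has no jointly non-missing variants."""


@dataclass
class GenotypeMatrix:
    """n individuals x k bi-allelic variants, dosage coded.

    Parameters
    ----------
    dosages:
        Integer array of shape (n, k) with entries in {0, 1, 2} or
        :data:`MISSING` (-1) for a missing call.
    sample_ids, variant_ids:
        Row and column labels.
    maf:
        Optional per-variant B-allele (minor allele) frequencies in
        [0, 0.5], e.g. the true frequencies of a simulation.
    """

    dosages: np.ndarray
    sample_ids: list[str]
    variant_ids: list[str]
    maf: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D (samples x variants) array")
        n, k = self.dosages.shape
        if n < 2 or k < 1:
            raise ValueError(f"need at least 2 samples and 1 variant, got {n} x {k}")
        if len(self.sample_ids) != n or len(self.variant_ids) != k:
            raise ValueError("sample_ids/variant_ids do not match dosage shape")
        valid = np.isin(self.dosages, (MISSING, 0, 1, 2))
        if not valid.all():
            bad = np.unique(self.dosages[~valid])
            raise ValueError(f"invalid dosage values {bad}; expected 0/1/2 or {MISSING}")
        if self.maf is not None:
            self.maf = np.asarray(self.maf, dtype=float)
            if self.maf.shape != (k,):
                raise ValueError("maf must be a length-k vector")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def observed_allele_freq(self) -> np.ndarray:
        """Per-variant B-allele frequency from non-missing calls.

        Variants with no calls at all get frequency NaN.
        """
        d = self.dosages
        obs = d != MISSING
        n_called = obs.sum(axis=0)
        with np.errstate(invalid="ignore"):
            return np.where(obs, d, 0).sum(axis=0) / (2.0 * n_called)

    def observed_maf(self) -> np.ndarray:
        """Per-variant minor allele frequency (folded allele frequency)."""
        p = self.observed_allele_freq()
        return np.minimum(p, 1.0 - p)


@dataclass
class PairComposition:
    """Six genotype-pair counts for one pair of individuals."""

    counts: np.ndarray  # (6,) int, (k00, k10, k20, k11, k21, k22)
    total: int
    pair: tuple[str, str] = ("", "")
    x: np.ndarray | None = field(default=None)  # closed composition, if computed

    def close(self, zero_policy: str = "replace0.5") -> np.ndarray:
        self.x = close_composition(self.counts, zero_policy=zero_policy)
        return self.x


@dataclass
class IbsSummary:
    """Classical IBS summaries of one pair.

    m and s are the mean and *population* (divide-by-k) standard deviation of
    the per-variant IBS allele count; p0, p1, p2 are the fractions of variants
    sharing 0, 1, 2 alleles IBS.  They satisfy m = 1 - p0 + p2 and
    s**2 = p0*(1-p0) + p2*(1-p2) + 2*p0*p2 exactly.
    """

    m: float
    s: float
    p0: float
    p1: float
    p2: float


def ibs_count(g1: int, g2: int) -> int:
    """Number of IBS alleles shared by two dosages (symmetric, in {0,1,2})."""
    if g1 == MISSING or g2 == MISSING:
        raise MissingGenotypeError("missing genotype; exclude the variant before counting")
    if g1 not in (0, 1, 2) or g2 not in (0, 1, 2):
        raise ValueError(f"dosages must be in {{0,1,2}}, got ({g1}, {g2})")
    return int(_IBS[g1, g2])


def _pair_counts_array(gi: np.ndarray, gj: np.ndarray) -> np.ndarray:
    """Vectorised 6-category tally for two dosage vectors (missing excluded)."""
    keep = (gi != MISSING) & (gj != MISSING)
    codes = _CODE[gi[keep], gj[keep]]
    return np.bincount(codes, minlength=6).astype(np.int64)


def genotype_pair_counts(
    geno_i: Sequence[int] | np.ndarray,
    geno_j: Sequence[int] | np.ndarray,
    pair: tuple[str, str] = ("", ""),
) -> PairComposition:
    """Tally the six unordered genotype-pair categories over shared variants.

    Variants missing in either individual are excluded; the counts therefore
    sum to the number of jointly non-missing variants.
    """
    gi = np.asarray(geno_i)
    gj = np.asarray(geno_j)
    if gi.shape != gj.shape or gi.ndim != 1:
        raise ValueError("genotype vectors must be 1-D and of equal length")
    counts = _pair_counts_array(gi, gj)
    total = int(counts.sum())
    if total == 0:
        raise EmptyPairError(f"pair {pair}: no jointly non-missing variants")
    return PairComposition(counts=counts, total=total, pair=pair)


def close_composition(
    counts: Sequence[int] | np.ndarray,
    total: int | None = None,
    zero_policy: str = "replace0.5",
) -> np.ndarray:
    """Close a count vector to a strictly positive composition summing to 1.

    zero_policy:
      - ``"replace0.5"`` / ``"replace1"``: zero counts are replaced by 0.5 / 1
        before closure (suitable when zeros are few).
      - ``"multiplicative"``: ratio-preserving multiplicative replacement with
        delta = 0.5/total on the closed scale; non-zero parts keep their
        mutual ratios exactly.
      - ``"none"``: zeros raise an error.
    """
    c = np.asarray(counts, dtype=float)
    if (c < 0).any():
        raise ValueError("counts must be non-negative")
    k = float(c.sum()) if total is None else float(total)
    if c.sum() <= 0:
        raise ValueError("all-zero counts cannot be closed to a composition")
    zeros = c == 0
    if zero_policy == "none":
        if zeros.any():
            raise ValueError(
                "zero counts present; choose a zero_policy "
                "(replace0.5, replace1, multiplicative)"
            )
        x = c / c.sum()
    elif zero_policy in ("replace0.5", "replace1"):
        repl = 0.5 if zero_policy == "replace0.5" else 1.0
        c = np.where(zeros, repl, c)
        x = c / c.sum()
    elif zero_policy == "multiplicative":
        x = c / k
        delta = 0.5 / k
        n_zero = int(zeros.sum())
        x = np.where(zeros, delta, x * (1.0 - n_zero * delta))
        x = x / x.sum()
    else:
        raise ValueError(f"unknown zero_policy {zero_policy!r}")
    return x


def ibs_summary(counts: Sequence[int] | np.ndarray) -> IbsSummary:
    """IBS summary statistics from a six-category count vector."""
    c = np.asarray(counts, dtype=float)
    k = c.sum()
    if k <= 0:
        raise EmptyPairError("empty pair: zero total count")
    k00, k10, k20, k11, k21, k22 = c
    p0 = k20 / k
    p1 = (k10 + k21) / k
    p2 = (k00 + k11 + k22) / k
    m = p1 + 2.0 * p2
    var = p1 + 4.0 * p2 - m * m  # E[IBS^2] - m^2, population variance
    s = float(np.sqrt(max(var, 0.0)))
    return IbsSummary(m=float(m), s=s, p0=float(p0), p1=float(p1), p2=float(p2))


def iter_pairs(n: int) -> Iterator[tuple[int, int]]:
    """Unordered pair indices in lexicographic order (i < j)."""
    for i in range(n - 1):
        for j in range(i + 1, n):
            yield i, j


def all_pair_compositions(G: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray, list[tuple[str, str]]]:
    """Six-category counts for all q = n(n-1)/2 unordered pairs.

    Returns ``(counts, totals, pairs)`` where ``counts`` is q x 6 with rows in
    lexicographic order by sample index, ``totals`` the per-pair jointly
    non-missing variant counts, and ``pairs`` the sample-id tuples.
    """
    n = G.n_samples
    q = n * (n - 1) // 2
    counts = np.zeros((q, 6), dtype=np.int64)
    pairs: list[tuple[str, str]] = []
    d = G.dosages
    for row, (i, j) in enumerate(iter_pairs(n)):
        counts[row] = _pair_counts_array(d[i], d[j])
        if counts[row].sum() == 0:
            raise EmptyPairError(
                f"pair ({G.sample_ids[i]}, {G.sample_ids[j]}): "
                "no jointly non-missing variants"
            )
        pairs.append((G.sample_ids[i], G.sample_ids[j]))
    totals = counts.sum(axis=1)
    return counts, totals, pairs


def pair_table(G: GenotypeMatrix) -> pd.DataFrame:
    """Per-pair counts plus classical IBS summaries as a tidy table."""
    counts, totals, pairs = all_pair_compositions(G)
    recs = []
    for row, (a, b) in enumerate(pairs):
        summ = ibs_summary(counts[row])
        recs.append(
            {
                "pair_i": a,
                "pair_j": b,
                "k00": counts[row, 0],
                "k10": counts[row, 1],
                "k20": counts[row, 2],
                "k11": counts[row, 3],
                "k21": counts[row, 4],
                "k22": counts[row, 5],
                "k": totals[row],
                "p0": summ.p0,
                "p1": summ.p1,
                "p2": summ.p2,
                "m": summ.m,
                "s": summ.s,
            }
        )
    return pd.DataFrame.from_records(recs)
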