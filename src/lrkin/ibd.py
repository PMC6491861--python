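"""Classical IBD-based relatedness estimators for genotype pairs.

Cotterman coefficients (k0, k1, k2) — the probabilities of a pair sharing
0, 1 or 2 alleles identical by descent at a locus — are estimated by the
method of moments under HWE from the observed IBS class counts, and kinship
by the allele-frequency-free KING estimator for homogeneous populations.
Co-ancestry is theta = k1/2 + k2 and kinship phi = theta/2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .composition import (
    MISSING,
    EmptyPairError,
    GenotypeMatrix,
    _pair_counts_array,
    iter_pairs,
)

__all__ = [
    "CottermanEstimate",
    "mom_cotterman",
    "mom_from_counts",
    "king_kinship",
    "king_from_counts",
    "coancestry",
    "pairwise_king",
]


@dataclass
class CottermanEstimate:
    """Estimated IBD-sharing probabilities and derived coefficients."""

    k0: float
    k1: float
    k2: float
    theta: float
    phi: float
    method: str = "mom"


def coancestry(k0: float, k1: float, k2: float) -> tuple[float, float]:
    """Co-ancestry theta = k1/2 + k2 and kinship phi = theta/2."""
    theta = k1 / 2.0 + k2
    return theta, theta / 2.0


def _truncate_simplex(k0: float, k1: float, k2: float) -> tuple[float, float, float]:
    k = np.clip([k0, k1, k2], 0.0, None)
    s = k.sum()
    if s == 0:  # pathological; fall back to "unrelated"
        return 1.0, 0.0, 0.0
    k = k / s
    return float(k[0]), float(k[1]), float(k[2])


def _estimate(n_ibs: np.ndarray, e: dict[str, float], method: str) -> CottermanEstimate:
    """Sequential moment solution from IBS class counts and expectation sums."""
    k0 = n_ibs[0] / e["ibs0_ibd0"] if e["ibs0_ibd0"] > 0 else 0.0
    k1 = (n_ibs[1] - k0 * e["ibs1_ibd0"]) / e["ibs1_ibd1"] if e["ibs1_ibd1"] > 0 else 0.0
    k2 = 1.0 - k0 - k1
    k0, k1, k2 = _truncate_simplex(k0, k1, k2)
    theta, phi = coancestry(k0, k1, k2)
    return CottermanEstimate(k0=k0, k1=k1, k2=k2, theta=theta, phi=phi, method=method)


def mom_cotterman(
    geno_i: Sequence[int] | np.ndarray,
    geno_j: Sequence[int] | np.ndarray,
    allele_freqs: Sequence[float] | np.ndarray,
) -> CottermanEstimate:
    """Method-of-moments Cotterman estimate for one pair.

    ``allele_freqs`` are per-variant B-allele frequencies (cohort estimates or
    the true simulation values).  The observed counts of IBS class 0/1/2 over
    jointly non-missing polymorphic variants are equated to their HWE
    expectations: with q = 1 - p,

        P(IBS0|IBD0) = 2 p^2 q^2
        P(IBS1|IBD0) = 4 p^3 q + 4 p q^3     P(IBS1|IBD1) = 2 p^2 q + 2 p q^2
        P(IBS2|IBD2) = 1

    k0 is solved from the IBS0 count, k1 from the IBS1 count given k0, and
    k2 by complement; negative solutions are truncated to zero and the triple
    renormalised to sum one.  Monomorphic variants are excluded.
    """
    gi = np.asarray(geno_i)
    gj = np.asarray(geno_j)
    p = np.asarray(allele_freqs, dtype=float)
    keep = (gi != MISSING) & (gj != MISSING) & (p > 0) & (p < 1)
    if not keep.any():
        raise EmptyPairError("no jointly typed polymorphic variants")
    gi, gj, p = gi[keep], gj[keep], p[keep]
    q = 1.0 - p
    ibs = 2 - np.abs(gi - gj)
    n_ibs = np.bincount(ibs, minlength=3).astype(float)
    e = {
        "ibs0_ibd0": float((2 * p**2 * q**2).sum()),
        "ibs1_ibd0": float((4 * p**3 * q + 4 * p * q**3).sum()),
        "ibs1_ibd1": float((2 * p**2 * q + 2 * p * q**2).sum()),
    }
    return _estimate(n_ibs / len(p), {k: v / len(p) for k, v in e.items()}, "mom")


def mom_from_counts(counts: Sequence[int] | np.ndarray, p: float) -> CottermanEstimate:
    """Moment estimate from six-category counts at a single allele frequency.

    Valid when every variant has the same (known) B-allele frequency, as in
    the HWE simulator; the IBS class counts are IBS0 = k20,
    IBS1 = k10 + k21, IBS2 = k00 + k11 + k22.
    """
    c = np.asarray(counts, dtype=float)
    k = c.sum()
    if k <= 0:
        raise EmptyPairError("empty pair")
    if not 0 < p < 1:
        raise ValueError("allele frequency must be in (0, 1)")
    q = 1.0 - p
    n_ibs = np.array([c[2], c[1] + c[4], c[0] + c[3] + c[5]]) / k
    e = {
        "ibs0_ibd0": 2 * p**2 * q**2,
        "ibs1_ibd0": 4 * p**3 * q + 4 * p * q**3,
        "ibs1_ibd1": 2 * p**2 * q + 2 * p * q**2,
    }
    return _estimate(n_ibs, e, "mom")


def king_from_counts(counts: Sequence[int] | np.ndarray, n_het_i: int, n_het_j: int) -> float:
    """KING kinship from six-category counts and per-member het totals.

    Homogeneous-population (within-family) form:
    phi_hat = (N_AaAa - 2 N_AAaa) / (N_het(i) + N_het(j)), with
    N_AaAa = k11 and N_AAaa = k20.
    """
    denom = n_het_i + n_het_j
    if denom == 0:
        raise ValueError("KING kinship undefined: neither individual has heterozygotes")
    c = np.asarray(counts, dtype=float)
    return float((c[3] - 2.0 * c[2]) / denom)


def king_kinship(
    geno_i: Sequence[int] | np.ndarray, geno_j: Sequence[int] | np.ndarray
) -> float:
    """Allele-frequency-free KING kinship estimate for one pair."""
    gi = np.asarray(geno_i)
    gj = np.asarray(geno_j)
    keep = (gi != MISSING) & (gj != MISSING)
    if not keep.any():
        raise EmptyPairError("no jointly non-missing variants")
    gi, gj = gi[keep], gj[keep]
    counts = _pair_counts_array(gi, gj)
    return king_from_counts(counts, int((gi == 1).sum()), int((gj == 1).sum()))


def pairwise_king(G: GenotypeMatrix) -> pd.DataFrame:
    """KING kinship for every unordered pair of a genotype matrix.

    Returns a tidy frame with integer sample indices ``i`` < ``j``, the
    sample ids, and ``phi``; input to the unrelated-subset selection.
    """
    recs = []
    d = G.dosages
    for i, j in iter_pairs(G.n_samples):
        recs.append(
            {
                "i": i,
                "j": j,
                "pair_i": G.sample_ids[i],
                "pair_j": G.sample_ids[j],
                "phi": king_kinship(d[i], d[j]),
            }
        )
    return pd.DataFrame.from_records(recs)
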