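"""Variant quality filters: missingness, MAF, and the Hardy-Weinberg exact
mid p-value.

The HWE test uses the Levene-Haldane exact distribution of the heterozygote
count conditional on the allele counts; the mid p-value sums the
probabilities of outcomes less probable than the observed one plus half the
probability of outcomes exactly as probable.  LD pruning is deliberately not
performed here — inputs are assumed pre-pruned by external tooling.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.special import gammaln

from .composition import MISSING, GenotypeMatrix

__all__ = ["hwe_exact_midp", "filter_variants"]

log = logging.getLogger(__name__)


def _het_distribution(n_a: int, n_b: int) -> tuple[np.ndarray, np.ndarray]:
    """Support and probabilities of the heterozygote count given allele counts."""
    n = (n_a + n_b) // 2
    n_min = min(n_a, n_b)
    n_ab = np.arange(n_min % 2, n_min + 1, 2)
    n_aa = (n_a - n_ab) // 2
    n_bb = (n_b - n_ab) // 2
    logp = (
        gammaln(n + 1)
        - gammaln(n_aa + 1)
        - gammaln(n_ab + 1)
        - gammaln(n_bb + 1)
        + n_ab * np.log(2.0)
        + gammaln(n_a + 1)
        + gammaln(n_b + 1)
        - gammaln(2 * n + 1)
    )
    p = np.exp(logp)
    return n_ab, p / p.sum()


def hwe_exact_midp(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact Hardy-Weinberg mid p-value for one bi-allelic variant.

    For a monomorphic variant the conditional distribution has a single
    outcome and the mid-p is 0.5 by convention.
    """
    if min(n_aa, n_ab, n_bb) < 0 or n_aa + n_ab + n_bb < 1:
        raise ValueError("genotype counts must be non-negative with at least one sample")
    n_a = 2 * n_aa + n_ab
    n_b = 2 * n_bb + n_ab
    if n_a == 0 or n_b == 0:
        return 0.5
    support, probs = _het_distribution(n_a, n_b)
    p_obs = probs[support == n_ab][0]
    equal = np.isclose(probs, p_obs, rtol=1e-9, atol=0.0)
    below = (probs < p_obs) & ~equal
    return float(probs[below].sum() + 0.5 * probs[equal].sum())


def filter_variants(
    G: GenotypeMatrix,
    maf_threshold: float = 0.40,
    hwe_midp_threshold: float = 0.05,
    max_missingness: float = 0.0,
) -> GenotypeMatrix:
    """Keep variants passing missingness, MAF and HWE mid-p thresholds.

    Defaults follow common relatedness QC for highly informative panels:
    complete variants only, MAF strictly above 0.40 and HWE exact mid-p
    strictly above 0.05.  Per-filter drop counts are logged.
    """
    d = G.dosages
    n = G.n_samples
    miss_rate = (d == MISSING).sum(axis=0) / n
    pass_miss = miss_rate <= max_missingness
    maf = G.observed_maf()
    pass_maf = np.nan_to_num(maf, nan=0.0) > maf_threshold
    midp = np.ones(G.n_variants)
    for v in np.flatnonzero(pass_miss & pass_maf):
        col = d[:, v]
        col = col[col != MISSING]
        midp[v] = hwe_exact_midp(
            int((col == 0).sum()), int((col == 1).sum()), int((col == 2).sum())
        )
    pass_hwe = midp > hwe_midp_threshold
    keep = pass_miss & pass_maf & pass_hwe
    log.info(
        "filter_variants: %d/%d kept (missingness dropped %d, MAF dropped %d, HWE dropped %d)",
        keep.sum(),
        G.n_variants,
        (~pass_miss).sum(),
        (pass_miss & ~pass_maf).sum(),
        (pass_miss & pass_maf & ~pass_hwe).sum(),
    )
    if not keep.any():
        raise ValueError("no variants survive the filters")
    return GenotypeMatrix(
        dosages=d[:, keep],
        sample_ids=list(G.sample_ids),
        variant_ids=[v for v, k in zip(G.variant_ids, keep) if k],
        maf=None if G.maf is None else G.maf[keep],
    )
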