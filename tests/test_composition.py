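"""Genotype-pair counting, closure and IBS summary statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lrkin.composition import (
    MISSING,
    EmptyPairError,
    MissingGenotypeError,
    all_pair_compositions,
    close_composition,
    genotype_pair_counts,
    ibs_count,
    ibs_summary,
    pair_table,
)


@pytest.mark.parametrize(
    "g1,g2,expected",
    [
        (0, 0, 2),  # AA/AA
        (0, 1, 1),  # AA/AB
        (0, 2, 0),  # AA/BB: opposite homozygotes share nothing
        (1, 1, 2),  # AB/AB
        (1, 2, 1),
        (2, 2, 2),
    ],
)
def test_ibs_count_matches_allele_sharing_table(g1, g2, expected):
    assert ibs_count(g1, g2) == expected
    assert ibs_count(g2, g1) == expected


def test_ibs_count_rejects_missing_and_invalid():
    with pytest.raises(MissingGenotypeError):
        ibs_count(MISSING, 0)
    with pytest.raises(ValueError):
        ibs_count(0, 3)


def test_pair_counts_hand_example():
    pc = genotype_pair_counts([0, 1, 2, 1, 0], [0, 0, 2, 2, 1])
    assert pc.counts.tolist() == [1, 2, 0, 0, 1, 1]
    assert pc.total == 5


def test_pair_counts_identical_homozygous_vectors():
    g = np.array([0, 2, 0, 2, 2, 0])
    pc = genotype_pair_counts(g, g)
    # MZ-like pair without heterozygotes: only k00 and k22 populated
    assert pc.counts[[1, 2, 3, 4]].tolist() == [0, 0, 0, 0]
    assert pc.counts[0] + pc.counts[5] == len(g)


def _brute_force_counts(gi, gj):
    """Per-variant loop oracle for the six-category tally."""
    order = {(0, 0): 0, (1, 0): 1, (2, 0): 2, (1, 1): 3, (2, 1): 4, (2, 2): 5}
    counts = [0] * 6
    for a, b in zip(gi, gj):
        if a == MISSING or b == MISSING:
            continue
        counts[order[(max(a, b), min(a, b))]] += 1
    return counts


def test_pair_counts_match_brute_force_oracle(rng):
    gi = rng.integers(0, 3, 1000)
    gj = rng.integers(0, 3, 1000)
    gi[rng.random(1000) < 0.1] = MISSING
    gj[rng.random(1000) < 0.1] = MISSING
    pc = genotype_pair_counts(gi, gj)
    assert pc.counts.tolist() == _brute_force_counts(gi, gj)
    assert pc.total == sum((gi != MISSING) & (gj != MISSING))


@given(st.lists(st.integers(-1, 2), min_size=2, max_size=60), st.data())
@settings(max_examples=50, deadline=None)
def test_pair_counts_symmetric_and_conserved(gi, data):
    gj = data.draw(st.lists(st.integers(-1, 2), min_size=len(gi), max_size=len(gi)))
    joint = sum(a != MISSING and b != MISSING for a, b in zip(gi, gj))
    if joint == 0:
        with pytest.raises(EmptyPairError):
            genotype_pair_counts(gi, gj)
        return
    a = genotype_pair_counts(gi, gj)
    b = genotype_pair_counts(gj, gi)
    assert a.counts.tolist() == b.counts.tolist()
    assert a.total == joint == a.counts.sum()


def test_close_composition_uniform():
    x = close_composition([10] * 6)
    np.testing.assert_allclose(x, np.full(6, 1 / 6))


@pytest.mark.parametrize("policy,repl", [("replace0.5", 0.5), ("replace1", 1.0)])
def test_close_composition_count_replacement(policy, repl):
    counts = np.array([50, 30, 0, 10, 5, 5])
    x = close_composition(counts, zero_policy=policy)
    expected = np.where(counts == 0, repl, counts).astype(float)
    np.testing.assert_allclose(x, expected / expected.sum())
    assert (x > 0).all() and np.isclose(x.sum(), 1.0)


def test_multiplicative_replacement_preserves_nonzero_ratios():
    counts = np.array([40, 0, 0, 30, 20, 10])
    x = close_composition(counts, zero_policy="multiplicative")
    nz = counts > 0
    np.testing.assert_allclose(
        x[nz] / x[nz].sum(), counts[nz] / counts[nz].sum()
    )
    assert (x > 0).all() and np.isclose(x.sum(), 1.0)


def test_close_composition_errors():
    with pytest.raises(ValueError):
        close_composition([0, 0, 0, 0, 0, 0])
    with pytest.raises(ValueError):
        close_composition([1, 0, 2, 3, 4, 5], zero_policy="none")
    with pytest.raises(ValueError):
        close_composition([1, 2, 3, 4, 5, 6], zero_policy="bogus")


def test_ibs_summary_constant_sharing():
    s = ibs_summary([10, 0, 0, 5, 0, 5])  # all categories share 2 alleles
    assert (s.m, s.s, s.p0, s.p1, s.p2) == (2.0, 0.0, 0.0, 0.0, 1.0)


def test_ibs_summary_small_example():
    # per-variant IBS counts (0, 1, 2, 1): categories k20, k10, k00, k21
    s = ibs_summary([1, 1, 1, 0, 1, 0])
    assert s.p0 == s.p2 == 0.25
    assert s.m == pytest.approx(1.0)
    assert s.s == pytest.approx(np.sqrt(0.5))


@given(st.lists(st.integers(0, 1000), min_size=6, max_size=6).filter(lambda c: sum(c) > 0))
@settings(max_examples=100, deadline=None)
def test_ibs_summary_identities(counts):
    s = ibs_summary(counts)
    assert s.p0 + s.p1 + s.p2 == pytest.approx(1.0)
    assert s.m == pytest.approx(1.0 - s.p0 + s.p2, abs=1e-12)
    assert s.s**2 == pytest.approx(
        s.p0 * (1 - s.p0) + s.p2 * (1 - s.p2) + 2 * s.p0 * s.p2, abs=1e-12
    )


def test_all_pair_compositions_small_and_consistent(random_genotypes):
    counts, totals, pairs = all_pair_compositions(random_genotypes)
    n = random_genotypes.n_samples
    assert counts.shape == (n * (n - 1) // 2, 6)
    assert pairs[0] == ("I0", "I1") and pairs[-1] == ("I8", "I9")
    d = random_genotypes.dosages
    row = 0
    for i in range(n - 1):
        for j in range(i + 1, n):
            assert counts[row].tolist() == _brute_force_counts(d[i], d[j])
            row += 1
    np.testing.assert_array_equal(totals, counts.sum(axis=1))


def test_pair_table_columns(random_genotypes):
    tab = pair_table(random_genotypes)
    assert list(tab.columns) == [
        "pair_i", "pair_j", "k00", "k10", "k20", "k11", "k21", "k22",
        "k", "p0", "p1", "p2", "m", "s",
    ]
    np.testing.assert_allclose(tab["m"], 1 - tab["p0"] + tab["p2"])
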