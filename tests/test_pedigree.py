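"""Founder simulation and Mendelian gene dropping with IBD tracking."""

import numpy as np
import pytest

from lrkin.composition import GenotypeMatrix
from lrkin.pedigree import (
    RELATIONSHIPS,
    HweFounders,
    PoolFounders,
    build_reference_set,
    gene_drop,
    realized_ibd_fractions,
    simulate_founders,
)


def test_founders_follow_hwe_at_half():
    G = simulate_founders(300, 0.5, 2000, seed=1)
    frac = [(G.dosages == g).mean() for g in (0, 1, 2)]
    np.testing.assert_allclose(frac, [0.25, 0.5, 0.25], atol=0.01)


def test_founders_monomorphic_and_deterministic():
    G = simulate_founders(5, 0.0, 50, seed=3)
    assert (G.dosages == 0).all()
    a = simulate_founders(8, 0.3, 100, seed=42)
    b = simulate_founders(8, 0.3, 100, seed=42)
    np.testing.assert_array_equal(a.dosages, b.dosages)


def test_invalid_maf_rejected():
    with pytest.raises(ValueError):
        HweFounders(0.7, 10)
    with pytest.raises(ValueError):
        HweFounders(-0.1, 10)


def test_po_child_between_opposite_homozygotes():
    # Parents fixed at dosage 0 and 2: the child is heterozygous everywhere
    # and the (parent, child) pair never hits the k20 category.
    pool = GenotypeMatrix(
        dosages=np.array([[0] * 30, [2] * 30], dtype=np.int8),
        sample_ids=["P0", "P2"],
        variant_ids=[f"v{i}" for i in range(30)],
    )
    res = gene_drop("PO", PoolFounders(pool), seed=5)
    child = res.geno_j if set(res.geno_j) == {1} else res.geno_i
    assert (child == 1).all()
    both = np.stack([res.geno_i, res.geno_j])
    assert not ((both.min(axis=0) == 0) & (both.max(axis=0) == 2)).any()


def test_mz_pair_is_identical():
    res = gene_drop("MZ", HweFounders(0.4, 500), seed=9, track_ibd=True)
    np.testing.assert_array_equal(res.geno_i, res.geno_j)
    assert realized_ibd_fractions(res) == (0.0, 0.0, 1.0)


def test_po_ibd_exactly_one():
    res = gene_drop("PO", HweFounders(0.5, 800), seed=10, track_ibd=True)
    assert realized_ibd_fractions(res) == (0.0, 1.0, 0.0)


def test_untracked_pair_has_no_ibd():
    res = gene_drop("FS", HweFounders(0.5, 100), seed=11)
    with pytest.raises(ValueError):
        realized_ibd_fractions(res)


def test_insufficient_founders():
    pool = GenotypeMatrix(
        dosages=np.array([[0, 1], [1, 2]], dtype=np.int8),
        sample_ids=["a", "b"],
        variant_ids=["v1", "v2"],
    )
    with pytest.raises(ValueError):
        gene_drop("HS", PoolFounders(pool), seed=1)  # needs 3 founders


@pytest.mark.parametrize(
    "label,expected",
    [
        ("FS", (0.25, 0.5, 0.25)),
        ("HS", (0.5, 0.5, 0.0)),
        ("3/4S-FS", (0.375, 0.5, 0.125)),
        ("FC", (0.75, 0.25, 0.0)),
    ],
)
def test_mean_realized_ibd_matches_expectations(small_reference, label, expected):
    """Tracked gene dropping recovers the textbook IBD probabilities."""
    if label in small_reference.labels:
        f = small_reference.ibd_fractions[small_reference.labels == label]
    else:  # pragma: no cover - all labels are present in the fixture
        raise AssertionError
    mean = f.mean(axis=0)
    se = f.std(axis=0, ddof=1) / np.sqrt(len(f))
    for got, exp, e in zip(mean, expected, se):
        assert abs(got - exp) <= max(3 * e, 1e-12)


def test_three_quarter_sibling_po_variant_kinship(rng):
    """The PO-flavoured 3/4S pedigree also realizes kinship 3/16."""
    founders = HweFounders(0.5, 4000)
    phis = []
    for seed in range(40):
        res = gene_drop("3/4S-PO", founders, seed=seed, track_ibd=True)
        f0, f1, f2 = realized_ibd_fractions(res)
        phis.append((f1 / 2 + f2) / 2)
    assert np.mean(phis) == pytest.approx(3 / 16, abs=0.01)


def test_reference_set_shape_labels_and_determinism():
    founders = HweFounders(0.5, 400)
    rels = ("FS", "HS", "UN")
    a = build_reference_set(rels, founders, 10, seed=77)
    b = build_reference_set(rels, founders, 10, seed=77)
    assert a.n_rows == 30
    assert (a.labels == np.repeat(rels, 10)).all()
    np.testing.assert_array_equal(a.counts, b.counts)
    c = build_reference_set(rels, founders, 10, seed=78)
    assert (a.counts != c.counts).any()


def test_po_structural_zero_exact_in_reference_set():
    ref = build_reference_set(["PO", "MZ"], HweFounders(0.5, 2000), 20, seed=3)
    po = ref.counts[ref.labels == "PO"]
    mz = ref.counts[ref.labels == "MZ"]
    assert (po[:, 2] == 0).all()  # k20
    assert (mz[:, [1, 2, 4]] == 0).all()  # k10, k20, k21


def test_offspring_conserve_pool_allele_frequency(rng):
    pool = simulate_founders(60, 0.3, 1500, seed=21)
    pool_freq = pool.dosages.mean() / 2
    freqs = []
    for seed in range(60):
        res = gene_drop("FS", PoolFounders(pool), seed=seed)
        freqs.append((res.geno_i.mean() + res.geno_j.mean()) / 4)
    assert np.mean(freqs) == pytest.approx(pool_freq, abs=0.01)


def test_degree_table():
    assert RELATIONSHIPS["PO"].degree == RELATIONSHIPS["FS"].degree == 1
    assert {RELATIONSHIPS[l].degree for l in ("HS", "GG", "AV")} == {2}
    assert RELATIONSHIPS["FC"].degree == 3
    assert RELATIONSHIPS["4th"].degree == 4
    assert RELATIONSHIPS["5th"].degree == 5
    assert RELATIONSHIPS["6th"].degree == 6
    assert np.isinf(RELATIONSHIPS["UN"].degree)
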