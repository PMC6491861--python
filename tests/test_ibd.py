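"""Cotterman coefficient and kinship estimation."""

import numpy as np
import pytest

from lrkin.composition import EmptyPairError
from lrkin.ibd import (
    coancestry,
    king_from_counts,
    king_kinship,
    mom_cotterman,
    mom_from_counts,
    pairwise_king,
)
from lrkin.pedigree import HweFounders, gene_drop, simulate_founders


@pytest.mark.parametrize(
    "k,expected_theta,expected_phi",
    [
        ((0.25, 0.5, 0.25), 0.5, 0.25),  # full siblings
        ((0.375, 0.5, 0.125), 0.375, 3 / 16),  # three-quarter siblings
        ((1.0, 0.0, 0.0), 0.0, 0.0),  # unrelated
        ((0.0, 1.0, 0.0), 0.5, 0.25),  # parent-offspring
    ],
)
def test_coancestry_from_cotterman(k, expected_theta, expected_phi):
    theta, phi = coancestry(*k)
    assert theta == pytest.approx(expected_theta)
    assert phi == pytest.approx(expected_phi)


def test_identical_vectors_estimate_full_ibd(rng):
    g = rng.integers(0, 3, 2000)
    p = np.full(2000, 0.5)
    est = mom_cotterman(g, g, p)
    assert est.k2 == pytest.approx(1.0)
    assert est.k0 == est.k1 == 0.0
    assert est.phi == pytest.approx(0.5)


def test_mom_truncation_keeps_simplex(rng):
    # unrelated pairs can produce negative raw k2; after truncation the
    # estimate must stay on the simplex
    founders = HweFounders(0.5, 3000)
    for seed in range(10):
        res = gene_drop("UN", founders, seed=seed)
        est = mom_cotterman(res.geno_i, res.geno_j, np.full(3000, 0.5))
        assert min(est.k0, est.k1, est.k2) >= 0
        assert est.k0 + est.k1 + est.k2 == pytest.approx(1.0)


@pytest.mark.parametrize(
    "label,expected",
    [("UN", (1, 0, 0)), ("FS", (0.25, 0.5, 0.25)), ("PO", (0, 1, 0))],
)
def test_mom_mean_recovers_reference_values(label, expected):
    founders = HweFounders(0.5, 5000)
    p = np.full(5000, 0.5)
    ks = []
    for seed in range(30):
        res = gene_drop(label, founders, seed=1000 + seed)
        est = mom_cotterman(res.geno_i, res.geno_j, p)
        ks.append((est.k0, est.k1, est.k2))
    # boundary relationships (UN, PO) sit on the simplex edge: truncation of
    # negative raw estimates biases the mean inward by roughly one SE
    np.testing.assert_allclose(np.mean(ks, axis=0), expected, atol=0.04)


def test_mom_tracks_realized_ibd_per_pair(small_reference):
    """The moment estimate follows each pair's realized IBD fractions.

    At 5,000 variants the per-pair sampling SE of the estimate is a few
    percent; require near-zero mean error and bound the worst pair at
    roughly 5 SE.
    """
    ests = np.array(
        [
            (lambda e: (e.k0, e.k1, e.k2))(mom_from_counts(c, 0.5))
            for c in small_reference.counts
        ]
    )
    err = ests - small_reference.ibd_fractions
    assert np.abs(err.mean(axis=0)).max() < 0.02
    assert np.abs(err).max() < 0.15


def test_monomorphic_variants_are_excluded(rng):
    g1 = np.array([0, 1, 2, 0, 0])
    g2 = np.array([0, 1, 2, 2, 0])
    p = np.array([0.5, 0.5, 0.5, 0.0, 1.0])  # last two monomorphic
    est = mom_cotterman(g1, g2, p)
    # only the three polymorphic variants count; all IBS2 -> k2 = 1
    assert est.k2 != pytest.approx(0.0)
    with pytest.raises(EmptyPairError):
        mom_cotterman(np.array([0]), np.array([0]), np.array([0.0]))


def test_king_mz_is_half(rng):
    g = rng.integers(0, 3, 1000)
    assume_het = (g == 1).sum()
    if assume_het == 0:
        g[0] = 1
    assert king_kinship(g, g) == pytest.approx(0.5)


@pytest.mark.parametrize("label,expected", [("PO", 0.25), ("UN", 0.0), ("HS", 0.125)])
def test_king_mean_matches_reference_kinship(label, expected):
    founders = HweFounders(0.5, 5000)
    phis = [
        king_kinship(*(lambda r: (r.geno_i, r.geno_j))(gene_drop(label, founders, seed=2000 + s)))
        for s in range(30)
    ]
    assert np.mean(phis) == pytest.approx(expected, abs=0.01)


def test_king_requires_heterozygotes():
    with pytest.raises(ValueError):
        king_from_counts([5, 0, 5, 0, 0, 5], 0, 0)


def test_king_agrees_with_mom_phi(small_reference):
    """Two independent kinship routes agree on first/second degree pairs."""
    sel = np.isin(small_reference.labels, ("FS", "HS"))
    for counts, (hi, hj) in zip(
        small_reference.counts[sel], small_reference.het_counts[sel]
    ):
        phi_king = king_from_counts(counts, int(hi), int(hj))
        phi_mom = mom_from_counts(counts, 0.5).phi
        assert phi_king == pytest.approx(phi_mom, abs=0.02)


def test_kinship_ordering_fs_34s_hs(small_reference):
    means = {
        lab: np.mean(
            [
                king_from_counts(c, int(hi), int(hj))
                for c, (hi, hj) in zip(
                    small_reference.counts[small_reference.labels == lab],
                    small_reference.het_counts[small_reference.labels == lab],
                )
            ]
        )
        for lab in ("FS", "3/4S-FS", "HS")
    }
    assert means["FS"] > means["3/4S-FS"] > means["HS"]


def test_pairwise_king_table():
    G = simulate_founders(6, 0.4, 800, seed=5)
    tab = pairwise_king(G)
    assert len(tab) == 15
    assert {"i", "j", "pair_i", "pair_j", "phi"} <= set(tab.columns)
    assert tab["phi"].abs().max() < 0.1  # unrelated founders
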