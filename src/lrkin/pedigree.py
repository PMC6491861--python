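"""Mendelian gene-drop simulation of related genotype pairs.

Founders carry two haplotypes per variant, drawn either from Hardy-Weinberg
equilibrium at stated allele frequencies or by resampling the rows of an
observed (approximately unrelated) genotype matrix.  Each non-founder inherits
one uniformly chosen allele from each parent, independently per variant, so
variants are treated as unlinked (an LD-pruned input is assumed).  Every
founder haplotype carries a unique tag; a pair's identity-by-descent state at
a variant is the number of tags its two members share, which gives exact
realized (f0, f1, f2) fractions without any estimation.

The registry :data:`RELATIONSHIPS` holds the standard pedigrees: MZ, PO, FS,
three-quarter siblings (FS and PO variants), HS, GG, AV, FC (= 3rd degree),
4th (first cousins once removed), 5th (second cousins), 6th (second cousins
once removed) and UN.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .composition import GenotypeMatrix, _pair_counts_array

__all__ = [
    "RelationshipSpec",
    "RELATIONSHIPS",
    "DEGREE_OF",
    "GeneDropResult",
    "ReferencePairSet",
    "HweFounders",
    "PoolFounders",
    "simulate_founders",
    "gene_drop",
    "realized_ibd_fractions",
    "build_reference_set",
]


@dataclass(frozen=True)
class RelationshipSpec:
    """A pedigree identifying two target individuals.

    ``members`` lists (id, parent1, parent2) in topological order; founders
    have parents ``None``.  ``degree`` is the conventional degree of
    relationship (0 for MZ, 1 for PO/FS, 2 for HS/GG/AV, ... and ``inf`` for
    UN; three-quarter siblings get 1.5, matching their kinship of 3/16
    between first and second degree).
    """

    label: str
    degree: float
    members: tuple[tuple[str, str | None, str | None], ...]
    target: tuple[str, str]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for name, p1, p2 in self.members:
            if (p1 is None) != (p2 is None):
                raise ValueError(f"{name}: non-founders need exactly two parents")
            if p1 is not None and (p1 not in seen or p2 not in seen):
                raise ValueError(f"{name}: parents must precede the child (acyclic order)")
            seen.add(name)
        for t in self.target:
            if t not in seen:
                raise ValueError(f"target {t} not in pedigree")

    @property
    def founders(self) -> list[str]:
        return [name for name, p1, _ in self.members if p1 is None]

    @property
    def n_founders(self) -> int:
        return len(self.founders)


def _spec(label: str, degree: float, members, target) -> RelationshipSpec:
    return RelationshipSpec(label=label, degree=degree, members=tuple(members), target=target)


def _standard_relationships() -> dict[str, RelationshipSpec]:
    F = None
    rel = {}
    rel["UN"] = _spec("UN", math.inf, [("a", F, F), ("b", F, F)], ("a", "b"))
    rel["MZ"] = _spec("MZ", 0, [("f1", F, F), ("f2", F, F), ("c", "f1", "f2")], ("c", "c"))
    rel["PO"] = _spec("PO", 1, [("f1", F, F), ("f2", F, F), ("c", "f1", "f2")], ("f1", "c"))
    rel["FS"] = _spec(
        "FS",
        1,
        [("f1", F, F), ("f2", F, F), ("c1", "f1", "f2"), ("c2", "f1", "f2")],
        ("c1", "c2"),
    )
    # Three-quarter siblings: one shared parent; the unshared parents are FS
    # (default) or PO.  Both give kinship 3/16.
    rel["3/4S-FS"] = _spec(
        "3/4S-FS",
        1.5,
        [
            ("f1", F, F),
            ("f2", F, F),
            ("s", F, F),
            ("p1", "f1", "f2"),
            ("p2", "f1", "f2"),
            ("c1", "s", "p1"),
            ("c2", "s", "p2"),
        ],
        ("c1", "c2"),
    )
    rel["3/4S-PO"] = _spec(
        "3/4S-PO",
        1.5,
        [
            ("f1", F, F),
            ("f2", F, F),
            ("s", F, F),
            ("p2", "f1", "f2"),
            ("c1", "s", "f1"),
            ("c2", "s", "p2"),
        ],
        ("c1", "c2"),
    )
    rel["HS"] = _spec(
        "HS",
        2,
        [
            ("f1", F, F),
            ("f2", F, F),
            ("f3", F, F),
            ("c1", "f1", "f2"),
            ("c2", "f1", "f3"),
        ],
        ("c1", "c2"),
    )
    rel["GG"] = _spec(
        "GG",
        2,
        [
            ("f1", F, F),
            ("f2", F, F),
            ("f3", F, F),
            ("c1", "f1", "f2"),
            ("g1", "c1", "f3"),
        ],
        ("f1", "g1"),
    )
    rel["AV"] = _spec(
        "AV",
        2,
        [
            ("f1", F, F),
            ("f2", F, F),
            ("f3", F, F),
            ("c1", "f1", "f2"),
            ("c2", "f1", "f2"),
            ("g1", "c2", "f3"),
        ],
        ("c1", "g1"),
    )
    # First cousins and the remoter chain built on them.
    fc_members = [
        ("f1", F, F),
        ("f2", F, F),
        ("f3", F, F),
        ("f4", F, F),
        ("c1", "f1", "f2"),
        ("c2", "f1", "f2"),
        ("g1", "c1", "f3"),
        ("g2", "c2", "f4"),
    ]
    rel["FC"] = _spec("FC", 3, fc_members, ("g1", "g2"))
    rel["4th"] = _spec(
        "4th", 4, fc_members + [("f5", F, F), ("h1", "g1", "f5")], ("h1", "g2")
    )
    sc_members = fc_members + [("f5", F, F), ("f6", F, F), ("h1", "g1", "f5"), ("h2", "g2", "f6")]
    rel["5th"] = _spec("5th", 5, sc_members, ("h1", "h2"))
    rel["6th"] = _spec(
        "6th", 6, sc_members + [("f7", F, F), ("i1", "h1", "f7")], ("i1", "h2")
    )
    return rel


RELATIONSHIPS: dict[str, RelationshipSpec] = _standard_relationships()

#: Degree of relationship per label (used for tie-breaking in classification).
DEGREE_OF: dict[str, float] = {lab: spec.degree for lab, spec in RELATIONSHIPS.items()}
DEGREE_OF["3rd"] = 3.0
DEGREE_OF["2nd"] = 2.0
DEGREE_OF["3/4S"] = 1.5


class HweFounders:
    """Founder haplotypes drawn under Hardy-Weinberg equilibrium.

    ``maf`` is the B-allele frequency, a scalar or length-``n_snps`` vector in
    (0, 0.5] (0 is allowed for degenerate monomorphic tests).
    """

    def __init__(self, maf: float | Sequence[float], n_snps: int):
        maf_arr = np.broadcast_to(np.asarray(maf, dtype=float), (n_snps,))
        if (maf_arr < 0).any() or (maf_arr > 0.5).any():
            raise ValueError("maf must lie in [0, 0.5]")
        self.maf = np.array(maf_arr)
        self.n_snps = int(n_snps)

    def draw_haplotypes(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """(n, 2, k) array of 0/1 allele values."""
        return (rng.random((n, 2, self.n_snps)) < self.maf).astype(np.uint8)


class PoolFounders:
    """Founders resampled (rows drawn without replacement per pedigree) from
    an observed unrelated subset; conditions the reference set on the observed
    allele frequencies."""

    def __init__(self, G: GenotypeMatrix):
        if (G.dosages < 0).any():
            raise ValueError("founder pool must be complete (no missing calls)")
        self.G = G
        self.n_snps = G.n_variants

    def draw_haplotypes(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if n > self.G.n_samples:
            raise ValueError(
                f"pedigree needs {n} founders but the pool has {self.G.n_samples}"
            )
        rows = rng.choice(self.G.n_samples, size=n, replace=False)
        d = self.G.dosages[rows]
        # Split each dosage into two haplotypes; the (random) phase of
        # heterozygotes is irrelevant for unlinked transmission.
        h0 = (d == 2).astype(np.uint8)
        h1 = (d >= 1).astype(np.uint8)
        swap = rng.random(d.shape) < 0.5
        hap = np.stack([np.where(swap, h1, h0), np.where(swap, h0, h1)], axis=1)
        return hap


FounderSource = HweFounders | PoolFounders


def _as_source(founder_pool: FounderSource | GenotypeMatrix) -> FounderSource:
    if isinstance(founder_pool, GenotypeMatrix):
        return PoolFounders(founder_pool)
    return founder_pool


def simulate_founders(
    n: int, maf: float | Sequence[float], n_snps: int, seed: int | np.random.Generator = 0
) -> GenotypeMatrix:
    """Simulate ``n`` unrelated individuals under HWE at the given MAF(s)."""
    rng = np.random.default_rng(seed)
    src = HweFounders(maf, n_snps)
    hap = src.draw_haplotypes(n, rng)
    dos = hap.sum(axis=1).astype(np.int8)
    return GenotypeMatrix(
        dosages=dos,
        sample_ids=[f"S{i:04d}" for i in range(n)],
        variant_ids=[f"V{j:06d}" for j in range(n_snps)],
        maf=np.array(src.maf),
    )


@dataclass
class GeneDropResult:
    """One simulated pair: dosage vectors and, optionally, per-variant IBD."""

    geno_i: np.ndarray
    geno_j: np.ndarray
    label: str
    ibd: np.ndarray | None = None  # per-variant IBD state in {0,1,2}

    def ibd_fractions(self) -> tuple[float, float, float]:
        return realized_ibd_fractions(self)


def _drop(
    spec: RelationshipSpec,
    source: FounderSource,
    rng: np.random.Generator,
    track_ibd: bool,
) -> GeneDropResult:
    k = source.n_snps
    founder_names = spec.founders
    haps = source.draw_haplotypes(len(founder_names), rng)
    values: dict[str, np.ndarray] = {}
    tags: dict[str, np.ndarray] = {}
    for idx, name in enumerate(founder_names):
        values[name] = haps[idx]
        if track_ibd:
            t = np.empty((2, k), dtype=np.int32)
            t[0] = 2 * idx
            t[1] = 2 * idx + 1
            tags[name] = t
    for name, p1, p2 in spec.members:
        if p1 is None:
            continue
        v = np.empty((2, k), dtype=np.uint8)
        t = np.empty((2, k), dtype=np.int32) if track_ibd else None
        for slot, parent in enumerate((p1, p2)):
            choose = rng.integers(0, 2, size=k)
            pv = values[parent]
            v[slot] = np.where(choose == 0, pv[0], pv[1])
            if track_ibd:
                pt = tags[parent]
                t[slot] = np.where(choose == 0, pt[0], pt[1])
        values[name] = v
        if track_ibd:
            tags[name] = t
    a, b = spec.target
    ga = values[a].sum(axis=0).astype(np.int8)
    gb = values[b].sum(axis=0).astype(np.int8)
    ibd = None
    if track_ibd:
        if a == b:
            ibd = np.full(k, 2, dtype=np.int8)
        else:
            ta, tb = tags[a], tags[b]
            ibd = (
                ((ta[0] == tb[0]) | (ta[0] == tb[1])).astype(np.int8)
                + ((ta[1] == tb[0]) | (ta[1] == tb[1])).astype(np.int8)
            )
    if a == b:
        gb = ga.copy()
    return GeneDropResult(geno_i=ga, geno_j=gb, label=spec.label, ibd=ibd)


def gene_drop(
    spec: RelationshipSpec | str,
    founder_pool: FounderSource | GenotypeMatrix,
    seed: int | np.random.Generator = 0,
    track_ibd: bool = False,
) -> GeneDropResult:
    """Gene-drop one pair of the given relationship.

    ``founder_pool`` is an :class:`HweFounders`, a :class:`PoolFounders`, or a
    plain :class:`GenotypeMatrix` of (assumed unrelated) individuals to
    resample.  Founders are drawn without replacement within the pedigree.
    """
    if isinstance(spec, str):
        spec = RELATIONSHIPS[spec]
    source = _as_source(founder_pool)
    rng = np.random.default_rng(seed)
    return _drop(spec, source, rng, track_ibd)


def realized_ibd_fractions(pair: GeneDropResult) -> tuple[float, float, float]:
    """Realized fractions of variants in IBD state 0/1/2 for a tracked pair."""
    if pair.ibd is None:
        raise ValueError("pair was generated without IBD tracking")
    counts = np.bincount(pair.ibd, minlength=3)
    f = counts / counts.sum()
    return float(f[0]), float(f[1]), float(f[2])


@dataclass
class ReferencePairSet:
    """Labelled simulated pair compositions forming a training set."""

    counts: np.ndarray  # (n_rows, 6) genotype-pair counts
    labels: np.ndarray  # (n_rows,) relationship label per row
    het_counts: np.ndarray  # (n_rows, 2) heterozygous-variant count per member
    ibd_fractions: np.ndarray | None  # (n_rows, 3) realized (f0, f1, f2)
    config: dict = field(default_factory=dict)

    @property
    def n_rows(self) -> int:
        return self.counts.shape[0]

    def compositions(self, zero_policy: str = "replace0.5") -> np.ndarray:
        from .composition import close_composition

        return np.vstack(
            [close_composition(c, zero_policy=zero_policy) for c in self.counts]
        )


def build_reference_set(
    relationships: Sequence[RelationshipSpec | str],
    founder_pool: FounderSource | GenotypeMatrix,
    n_pairs_per_rel: int = 100,
    seed: int | np.random.SeedSequence = 0,
    track_ibd: bool = False,
) -> ReferencePairSet:
    """Simulate ``n_pairs_per_rel`` independent pairs of each relationship.

    Founders are redrawn independently for every pair (reuse across pairs is
    allowed when resampling a finite pool).  Per-pair random substreams are
    derived from one master seed, so the full set is reproducible.
    """
    specs = [RELATIONSHIPS[r] if isinstance(r, str) else r for r in relationships]
    source = _as_source(founder_pool)
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(len(specs) * n_pairs_per_rel)
    n_rows = len(specs) * n_pairs_per_rel
    counts = np.zeros((n_rows, 6), dtype=np.int64)
    het = np.zeros((n_rows, 2), dtype=np.int64)
    labels = np.empty(n_rows, dtype=object)
    ibd = np.zeros((n_rows, 3), dtype=float) if track_ibd else None
    row = 0
    for spec in specs:
        for _ in range(n_pairs_per_rel):
            rng = np.random.default_rng(children[row])
            res = _drop(spec, source, rng, track_ibd)
            counts[row] = _pair_counts_array(res.geno_i, res.geno_j)
            het[row, 0] = int((res.geno_i == 1).sum())
            het[row, 1] = int((res.geno_j == 1).sum())
            labels[row] = spec.label
            if track_ibd:
                ibd[row] = realized_ibd_fractions(res)
            row += 1
    config = {
        "n_pairs_per_rel": n_pairs_per_rel,
        "relationships": [s.label for s in specs],
        "n_snps": source.n_snps,
        "seed": ss.entropy,
    }
    if isinstance(source, HweFounders):
        maf = source.maf
        config["maf"] = float(maf[0]) if np.ptp(maf) == 0 else maf.copy()
    return ReferencePairSet(
        counts=counts, labels=labels.astype(str), het_counts=het, ibd_fractions=ibd, config=config
    )
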