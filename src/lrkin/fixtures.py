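"""Deterministic tiny cohort fixtures for integration tests and demos.

The generated cohort contains unrelated founders plus a PO trio, an FS pair
and an MZ duplicate, so the structural-zero screen, classification and IO
round-trips can all be exercised on an input of a few kilobytes.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .composition import GenotypeMatrix
from .genotypes import write_tsv, write_vcf
from .pedigree import HweFounders

__all__ = ["make_fixture_cohort", "make_fixtures"]


def make_fixture_cohort(seed: int = 0, n_unrelated: int = 12, n_snps: int = 150) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Build the fixture cohort in memory.

    Returns the genotype matrix and a metadata table listing the known
    related pairs (labels MZ, PO, FS).
    """
    rng = np.random.default_rng(seed)
    maf = rng.uniform(0.2, 0.5, size=n_snps)
    src = HweFounders(maf, n_snps)
    founders = src.draw_haplotypes(n_unrelated + 2, rng)  # extra founders -> parents of FS

    def child(pa: np.ndarray, pb: np.ndarray) -> np.ndarray:
        pick_a = rng.integers(0, 2, size=n_snps)
        pick_b = rng.integers(0, 2, size=n_snps)
        return np.stack([pa[pick_a, np.arange(n_snps)], pb[pick_b, np.arange(n_snps)]])

    haps = {f"U{i:02d}": founders[i] for i in range(n_unrelated)}
    # PO trio: child of U00 and U01.
    haps["TRIO_C"] = child(founders[0], founders[1])
    # FS pair: two children of the two extra founders (not in the cohort).
    haps["FS_A"] = child(founders[n_unrelated], founders[n_unrelated + 1])
    haps["FS_B"] = child(founders[n_unrelated], founders[n_unrelated + 1])
    sample_ids = list(haps)
    dos = np.vstack([haps[s].sum(axis=0, dtype=np.int8) for s in sample_ids])
    # MZ duplicate of U02.
    dos = np.vstack([dos, dos[sample_ids.index("U02")]])
    sample_ids.append("U02_DUP")
    G = GenotypeMatrix(
        dosages=dos,
        sample_ids=sample_ids,
        variant_ids=[f"V{j:04d}" for j in range(n_snps)],
        maf=maf,
    )
    meta = pd.DataFrame(
        [
            ("U02", "U02_DUP", "MZ"),
            ("U00", "TRIO_C", "PO"),
            ("U01", "TRIO_C", "PO"),
            ("FS_A", "FS_B", "FS"),
        ],
        columns=["pair_i", "pair_j", "label"],
    )
    return G, meta


def make_fixtures(seed: int = 0, outdir: str | Path = "fixtures") -> dict[str, Path]:
    """Write the fixture cohort as VCF + TSV with a sidecar metadata table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    G, meta = make_fixture_cohort(seed=seed)
    paths = {
        "vcf": outdir / "cohort.vcf",
        "tsv": outdir / "cohort.tsv",
        "meta": outdir / "known_pairs.tsv",
    }
    write_vcf(G, paths["vcf"])
    write_tsv(G, paths["tsv"])
    meta.to_csv(paths["meta"], sep="\t", index=False)
    return paths
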