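"""Genotype matrix readers and writers (VCF, PLINK text, TSV dosage).

Dosage convention: count of the B allele (0 = AA, 1 = AB, 2 = BB).  For VCF
the ALT allele maps to B; for PLINK .ped text the minor allele (computed from
the data, alphabetical tie-break) maps to B.  Multi-allelic and non-SNP
records are skipped with a logged count.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .composition import MISSING, GenotypeMatrix

__all__ = [
    "read_genotypes",
    "read_vcf",
    "read_plink_ped",
    "read_tsv",
    "write_vcf",
    "write_tsv",
]

log = logging.getLogger(__name__)


def read_genotypes(path: str | Path, format: str | None = None) -> GenotypeMatrix:
    """Read a genotype matrix, inferring the format from the suffix.

    ``format`` is one of ``vcf``, ``plink-ped``, ``tsv``; if omitted it is
    guessed (.vcf/.vcf.gz -> vcf, .ped -> plink-ped, .tsv/.txt -> tsv).
    """
    path = Path(path)
    if format is None:
        suffix = path.name.lower()
        if suffix.endswith((".vcf", ".vcf.gz")):
            format = "vcf"
        elif suffix.endswith(".ped"):
            format = "plink-ped"
        elif suffix.endswith((".tsv", ".txt")):
            format = "tsv"
        else:
            raise ValueError(f"cannot infer format of {path}")
    if format == "vcf":
        return read_vcf(path)
    if format == "plink-ped":
        return read_plink_ped(path)
    if format == "tsv":
        return read_tsv(path)
    raise ValueError(f"unknown format {format!r}")


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read bi-allelic SNP records from a VCF (v4.x) via cyvcf2."""
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    rows: list[np.ndarray] = []
    ids: list[str] = []
    skipped = 0
    for rec in vcf:
        if len(rec.ALT) != 1 or not rec.is_snp:
            skipped += 1
            continue
        gt = np.asarray(rec.gt_types, dtype=np.int8)  # 0/1/2, 3 = unknown
        gt[gt == 3] = MISSING
        rows.append(gt)
        ids.append(rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}")
    vcf.close()
    if skipped:
        log.info("read_vcf: skipped %d multi-allelic/non-SNP records", skipped)
    if not rows:
        raise ValueError(f"{path}: no usable bi-allelic SNP records")
    return GenotypeMatrix(
        dosages=np.vstack(rows).T, sample_ids=samples, variant_ids=ids
    )


def read_plink_ped(ped_path: str | Path, map_path: str | Path | None = None) -> GenotypeMatrix:
    """Read PLINK text .ped/.map files.

    The B allele per variant is the minor allele observed in the file
    (alphabetical tie-break); '0' denotes a missing allele.
    """
    ped_path = Path(ped_path)
    if map_path is None:
        map_path = ped_path.with_suffix(".map")
    variant_ids = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) < 4:
                raise ValueError(f"{map_path}:{lineno}: malformed .map record")
            variant_ids.append(fields[1])
    k = len(variant_ids)
    sample_ids: list[str] = []
    allele_rows: list[list[tuple[str, str]]] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * k:
                raise ValueError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * k} fields, got {len(fields)}"
                )
            sample_ids.append(fields[1])
            alleles = fields[6:]
            allele_rows.append([(alleles[2 * v], alleles[2 * v + 1]) for v in range(k)])
    n = len(sample_ids)
    dos = np.full((n, k), MISSING, dtype=np.int8)
    for v in range(k):
        seen: dict[str, int] = {}
        for r in range(n):
            for a in allele_rows[r][v]:
                if a != "0":
                    seen[a] = seen.get(a, 0) + 1
        if len(seen) > 2:
            raise ValueError(f"variant {variant_ids[v]}: more than two alleles")
        # minor allele = B; alphabetical tie-break; monomorphic -> all dosage 0
        ordered = sorted(seen.items(), key=lambda kv: (kv[1], kv[0]))
        b_allele = ordered[0][0] if len(ordered) == 2 else None
        for r in range(n):
            a1, a2 = allele_rows[r][v]
            if a1 == "0" or a2 == "0":
                continue
            dos[r, v] = (a1 == b_allele) + (a2 == b_allele) if b_allele else 0
    return GenotypeMatrix(dosages=dos, sample_ids=sample_ids, variant_ids=variant_ids)


def read_tsv(path: str | Path) -> GenotypeMatrix:
    """Read a TSV dosage matrix: rows samples, header row of variant ids."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    dos = df.to_numpy(dtype=float)
    dos = np.where(np.isnan(dos), MISSING, dos).astype(np.int8)
    return GenotypeMatrix(
        dosages=dos,
        sample_ids=[str(s) for s in df.index],
        variant_ids=[str(v) for v in df.columns],
    )


def write_tsv(G: GenotypeMatrix, path: str | Path) -> None:
    """Write the dosage matrix as TSV (missing as empty cell)."""
    df = pd.DataFrame(
        G.dosages.astype(float), index=G.sample_ids, columns=G.variant_ids
    ).replace(float(MISSING), np.nan)
    df.to_csv(path, sep="\t", na_rep="")


def write_vcf(G: GenotypeMatrix, path: str | Path, chrom: str = "1") -> None:
    """Write a minimal VCF v4.2 (GT only, REF=A ALT=B, positions 1..k)."""
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(G.sample_ids) + "\n")
        for v in range(G.n_variants):
            calls = "\t".join(gt_str[int(g)] for g in G.dosages[:, v])
            fh.write(
                f"{chrom}\t{v + 1}\t{G.variant_ids[v]}\tA\tC\t.\tPASS\t.\tGT\t{calls}\n"
            )
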