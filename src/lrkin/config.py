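"""Pipeline configuration: one dataclass covering filtering, simulation,
classification and output settings, loadable from YAML with flag overrides
applied by the CLI."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    input_path: str | None = None
    input_format: str | None = None  # vcf | plink-ped | tsv (None = infer)
    maf_threshold: float = 0.40
    hwe_midp_threshold: float = 0.05
    max_missingness: float = 0.0  # complete variants only by default
    zero_policy: str = "replace0.5"
    k20_threshold: float = 0.005  # structural-zero (PO/MZ) screen
    kinship_threshold: float = 0.05  # co-ancestry cut for the unrelated subset
    n_pcs: int = 3
    relationships: list[str] = field(
        default_factory=lambda: ["FC", "4th", "5th", "6th", "UN"]
    )
    n_pairs_per_rel: int = 100
    n_snps: int = 35_000
    maf: float = 0.5
    n_replicates: int = 25
    seed: int = 0
    output_dir: str = "lrkin_out"

    def __post_init__(self) -> None:
        if not 0 <= self.maf_threshold <= 0.5:
            raise ValueError("maf_threshold must be in [0, 0.5]")
        for name in ("hwe_midp_threshold", "max_missingness", "k20_threshold"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.kinship_threshold < 0:
            raise ValueError("kinship_threshold must be non-negative")
        if not 1 <= self.n_pcs <= 5:
            raise ValueError("n_pcs must be between 1 and 5")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
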