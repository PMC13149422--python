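"""Run configuration: a flat key/value record serialised as TOML.

Defaults mirror the study conditions: a 200-accession panel, canonical
31-mers with a per-sample count floor of 5, MAF ≥ 0.01, significance
thresholds −log10 p > 5 (primary) / ≥ 4 (fallback), ±50 kb candidate
windows and 600 dpi root scans.
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass
from pathlib import Path


@dataclass
class RunConfig:
    seed: int = 1

    # reference genome
    n_contigs: int = 1
    contig_length: int = 200_000
    n_genes: int = 10
    gene_length: int = 2_000

    # population
    n_accessions: int = 200
    snp_rate: float = 2e-5
    causal_freq: float = 0.3
    causal_beta: float = 1.5
    causal_length: int = 60
    n_neutral_loci: int = 40

    # reads
    read_length: int = 100
    coverage: float = 30.0
    error_rate: float = 0.0

    # k-mers
    k: int = 31
    min_count: int = 5
    maf_min: float = 0.01

    # association
    primary: float = 5.0
    fallback: float = 4.0

    # candidate windows
    half_width: int = 50_000

    # phenotype simulation (SDM-like trait, g/pot scale)
    mu: float = 4.82
    sigma_g2: float = 0.5
    sigma_e2: float = 1.0
    treatment_effect: float = -1.14
    n_replicates: int = 3

    # ΔRDM contrast groups
    n_extreme: int = 30
    n_pick: int = 10

    # root architecture
    dpi: float = 600.0
    rsa_canvas: tuple[int, int] = (900, 640)

    # input/output behaviour
    simulate: bool = True
    phenotype_tsv: str | None = None
    write_reads: bool = False
    write_matrix: bool = True

    def validate(self) -> None:
        if self.k % 2 == 0 or not 1 <= self.k <= 31:
            raise ValueError("k must be odd and in [1, 31]")
        if not 0 <= self.maf_min <= 0.5:
            raise ValueError("maf_min outside [0, 0.5]")
        if self.primary < self.fallback:
            raise ValueError("primary threshold below fallback")
        if self.half_width < 0 or self.dpi <= 0:
            raise ValueError("half_width must be >= 0 and dpi > 0")
        if self.causal_length < self.k:
            raise ValueError("causal segment must be at least k bases")

    @classmethod
    def from_toml(cls, path) -> "RunConfig":
        data = tomllib.loads(Path(path).read_text())
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - fields
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "rsa_canvas" in data:
            data["rsa_canvas"] = tuple(data["rsa_canvas"])
        return cls(**data)

    def to_toml(self, path) -> None:
        lines = []
        for f in dataclasses.fields(self):
            value = getattr(self, f.name)
            if value is None:
                continue
            if isinstance(value, bool):
                text = "true" if value else "false"
            elif isinstance(value, str):
                text = f'"{value}"'
            elif isinstance(value, tuple):
                text = "[" + ", ".join(str(v) for v in value) + "]"
            else:
                text = repr(value)
            lines.append(f"{f.name} = {text}")
        Path(path).write_text("\n".join(lines) + "\n")

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["rsa_canvas"] = list(d["rsa_canvas"])
        return d
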