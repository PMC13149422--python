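"""Plain-text interchange formats: FASTA, FASTQ, GFF3 and TSV tables.

All genomic coordinates are 1-based inclusive (GFF3 convention); the
TSV writers keep that convention so tables round-trip losslessly.
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

GFF3_COLUMNS = [
    "seqid", "source", "type", "start", "end",
    "score", "strand", "phase", "attributes",
]


def write_fasta(records: Mapping[str, str], path) -> None:
    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()]
    SeqIO.write(recs, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fastq(reads: Iterable[str], path, prefix: str = "read", quality_char: str = "I") -> None:
    """Write reads with a constant quality string (no quality model)."""
    with open(path, "w") as fh:
        for i, seq in enumerate(reads):
            fh.write(f"@{prefix}_{i}\n{seq}\n+\n{quality_char * len(seq)}\n")


def read_fastq(path) -> list[str]:
    return [str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fastq")]


def write_gff3(genes: pd.DataFrame, path, source: str = "peff") -> None:
    """Write gene rows; expects columns gene_id, contig, start, end, strand."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in genes.itertuples(index=False):
            fh.write(
                f"{row.contig}\t{source}\tgene\t{int(row.start)}\t{int(row.end)}"
                f"\t.\t{row.strand}\t.\tID={row.gene_id}\n"
            )


def read_gff3(path) -> pd.DataFrame:
    """Read gene records into a frame with gene_id, contig, start, end, strand."""
    raw = pd.read_csv(path, sep="\t", comment="#", header=None, names=GFF3_COLUMNS)
    raw = raw[raw["type"] == "gene"].copy()
    raw["gene_id"] = raw["attributes"].str.extract(r"ID=([^;]+)")
    out = raw[["gene_id", "seqid", "start", "end", "strand"]].rename(columns={"seqid": "contig"})
    return out.reset_index(drop=True)


def write_tsv(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
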