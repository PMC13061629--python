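"""Text-format readers and writers used by the pipeline.

All outputs are plain text (FASTA/FASTQ via Biopython, interval tracks as
BED/bedGraph, tables as TSV) so that every artefact is diffable and
checksummable.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = ["write_fasta", "read_fasta", "write_fastq", "write_bed",
           "write_bedgraph", "write_tsv", "read_tsv", "write_json",
           "sha256_of"]


def write_fasta(path, sequences: dict[str, str]) -> None:
    records = [SeqRecord(Seq(s), id=name, description="")
               for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fastq(path, reads, prefix: str = "read") -> None:
    """Write raw reads with constant Q30 qualities (synthetic data carries
    no base-call error model)."""
    with open(path, "w") as fh:
        for i, seq in enumerate(reads):
            fh.write(f"@{prefix}_{i}\n{seq}\n+\n{'I' * len(seq)}\n")


def write_bed(path, intervals: pd.DataFrame) -> None:
    """BED with chrom/start/end plus optional name/score/strand columns."""
    cols = ["chrom", "start", "end"]
    for extra in ("name", "pirna_id", "score", "strand"):
        if extra in intervals.columns and len(cols) < 6:
            cols.append(extra)
    intervals[cols].to_csv(path, sep="\t", header=False, index=False)


def write_bedgraph(path, track: pd.DataFrame) -> None:
    track[["chrom", "start", "end", "value"]].to_csv(
        path, sep="\t", header=False, index=False)


def write_tsv(path, df: pd.DataFrame, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def write_json(path, obj) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()
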