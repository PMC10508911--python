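"""FASTA and configuration I/O."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an id -> sequence map.

    Accepts single-line and wrapped dialects; duplicate ids raise.
    """
    sequences: dict[str, str] = {}
    with open(path) as handle:
        for record in SeqIO.parse(handle, "fasta"):
            if record.id in sequences:
                raise ValueError(f"duplicate FASTA id {record.id!r} in {path}")
            sequences[record.id] = str(record.seq).upper()
    return sequences


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 80) -> None:
    """Write an id -> sequence map as FASTA wrapped at ``width`` columns."""
    records = [SeqRecord(Seq(seq), id=str(sid), description="") for sid, seq in sequences.items()]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(records)
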