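"""Shared sequence helpers and light FASTA/FASTQ I/O wrappers."""

from __future__ import annotations

import os
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

VALID_BASES = frozenset("ACGTN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def validate_bases(seq: str, where: str = "sequence") -> None:
    if not set(seq) <= VALID_BASES:
        bad = sorted(set(seq) - VALID_BASES)
        raise ValueError(f"non-ACGTN characters {bad} in {where}")


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """FASTA as an ordered name -> uppercase sequence mapping."""
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate FASTA record id {rec.id!r} in {path}")
        records[rec.id] = str(rec.seq).upper()
    return records


def write_fasta(path: str | os.PathLike, records: Iterable[tuple[str, str]], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fastq_seqs(path: str | os.PathLike) -> Iterator[str]:
    """Yield uppercase read sequences from a FASTQ file."""
    with open(path) as fh:
        for _title, seq, _qual in FastqGeneralIterator(fh):
            yield seq.upper()


def write_fastq(path: str | os.PathLike, records: Iterable[tuple[str, str]]) -> int:
    """Write (id, seq) records with constant Phred+33 quality 'I'; returns count."""
    n = 0
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")
            n += 1
    return n
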