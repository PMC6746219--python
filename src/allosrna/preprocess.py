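"""Raw reads -> clean reads: adapter trimming, 18-30 nt length filter,
structural-RNA removal, and collapsing to unique sequences with multiplicities.
"""

from __future__ import annotations

import os
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from ._seq import read_fasta, read_fastq_seqs, revcomp, validate_bases

MIN_LEN = 18
MAX_LEN = 30


@dataclass(frozen=True)
class SmallRNARead:
    """A distinct clean-read sequence with its multiplicity in the library."""

    sequence: str
    count: int


@dataclass
class CleanStats:
    total_raw: int = 0
    trimmed_away: int = 0          # reads removed entirely by trimming
    length_filtered: int = 0
    structural_removed: int = 0
    clean: int = 0
    length_histogram: dict[int, int] = field(default_factory=dict)

    def as_row(self) -> dict:
        row = {"total_raw": self.total_raw, "trimmed_away": self.trimmed_away,
               "length_filtered": self.length_filtered,
               "structural_removed": self.structural_removed, "clean": self.clean}
        for length in range(MIN_LEN, MAX_LEN + 1):
            row[f"len_{length}"] = self.length_histogram.get(length, 0)
        return row


def trim_adapters(read: str, adapter3: str | None, adapter5: str | None = None,
                  min_overlap: int = 6) -> str | None:
    """Trim adapter remnants off both ends; returns None for a fully-adapter read.

    3' rule: the longest read suffix that exactly equals a prefix of the 3'
    adapter (at least ``min_overlap`` nt) is removed; the 5' rule is symmetric
    (longest read prefix equal to an adapter suffix).
    """
    validate_bases(read, "read")
    if adapter3:
        validate_bases(adapter3, "adapter3")
        for k in range(min(len(read), len(adapter3)), min_overlap - 1, -1):
            if read.endswith(adapter3[:k]):
                read = read[:-k]
                break
    if adapter5 and read:
        validate_bases(adapter5, "adapter5")
        for k in range(min(len(read), len(adapter5)), min_overlap - 1, -1):
            if read.startswith(adapter5[-k:]):
                read = read[k:]
                break
    return read if read else None


def filter_reads(reads: Iterable[str], min_len: int = MIN_LEN,
                 max_len: int = MAX_LEN) -> list[str]:
    """Keep reads with min_len <= length <= max_len and no N; order-preserving."""
    return [r for r in reads if min_len <= len(r) <= max_len and "N" not in r]


class StructuralFilter:
    """Exact-substring membership against structural RNAs and their reverse
    complements, precomputed for the clean-read length range."""

    def __init__(self, structural: dict[str, str],
                 min_len: int = MIN_LEN, max_len: int = MAX_LEN):
        self._kmers: dict[int, set[str]] = {k: set() for k in range(min_len, max_len + 1)}
        self.empty = not structural
        for seq in structural.values():
            for s in (seq.upper(), revcomp(seq.upper())):
                for k in self._kmers:
                    for i in range(0, len(s) - k + 1):
                        self._kmers[k].add(s[i:i + k])

    def __contains__(self, read: str) -> bool:
        kmers = self._kmers.get(len(read))
        return kmers is not None and read in kmers


def remove_structural(reads: Sequence[str],
                      structural: dict[str, str] | StructuralFilter) -> tuple[list[str], int]:
    """Drop reads that are exact substrings of any structural RNA (either strand).

    Returns (kept reads, number removed). An empty structural set keeps
    everything, with a warning.
    """
    filt = structural if isinstance(structural, StructuralFilter) else StructuralFilter(structural)
    if filt.empty:
        warnings.warn("empty structural-RNA reference: no reads removed", stacklevel=2)
        return list(reads), 0
    kept = [r for r in reads if r not in filt]
    return kept, len(reads) - len(kept)


def collapse(reads: Iterable[str]) -> list[SmallRNARead]:
    """One record per distinct sequence, ordered by count (desc) then sequence."""
    counts = Counter(reads)
    return [SmallRNARead(seq, n)
            for seq, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))]


def clean_library(raw_reads: Iterable[str], adapter3: str | None,
                  adapter5: str | None = None,
                  structural: dict[str, str] | StructuralFilter | None = None,
                  min_len: int = MIN_LEN, max_len: int = MAX_LEN,
                  min_overlap: int = 6) -> tuple[list[SmallRNARead], CleanStats]:
    """Full preprocessing of one library: trim -> length filter -> structural
    removal -> collapse. Returns collapsed clean reads and stage statistics."""
    stats = CleanStats()
    trimmed = []
    for read in raw_reads:
        stats.total_raw += 1
        t = trim_adapters(read.upper(), adapter3, adapter5, min_overlap)
        if t is None:
            stats.trimmed_away += 1
        else:
            trimmed.append(t)
    sized = filter_reads(trimmed, min_len, max_len)
    stats.length_filtered = len(trimmed) - len(sized)
    if structural is not None:
        clean, removed = remove_structural(sized, structural)
        stats.structural_removed = removed
    else:
        clean = sized
    stats.clean = len(clean)
    hist = Counter(len(r) for r in clean)
    stats.length_histogram = dict(sorted(hist.items()))
    return collapse(clean), stats


def clean_fastq(path: str | os.PathLike, adapter3: str | None,
                adapter5: str | None = None,
                structural_fasta: str | os.PathLike | None = None,
                **kwargs) -> tuple[list[SmallRNARead], CleanStats]:
    structural = read_fasta(structural_fasta) if structural_fasta else None
    return clean_library(read_fastq_seqs(path), adapter3, adapter5, structural, **kwargs)


def write_collapsed_fasta(path: str | os.PathLike, reads: Sequence[SmallRNARead]) -> None:
    """Collapsed-read FASTA in the `>seq{i}_x{count}` dialect."""
    with open(path, "w") as fh:
        for i, r in enumerate(reads, 1):
            fh.write(f">seq{i}_x{r.count}\n{r.sequence}\n")


def read_collapsed_fasta(path: str | os.PathLike) -> list[SmallRNARead]:
    out = []
    for name, seq in read_fasta(path).items():
        count = int(name.rsplit("_x", 1)[1])
        out.append(SmallRNARead(seq, count))
    return out
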