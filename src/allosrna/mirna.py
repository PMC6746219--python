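"""Conserved-miRNA identification and quantification.

A read is assigned to a known mature miRNA when it matches the reference
sequence with at most two mismatches (ungapped); expression is counted from
genome placements overlapping a mature-miRNA locus by at least one nucleotide
and normalised to reads per million (RPM) of the clean library.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .align import AlignmentHit, ExactIndex, Genome
from .preprocess import SmallRNARead

MAX_MISMATCHES = 2


@dataclass
class MatureMiRNA:
    """A reference mature miRNA with its exact-match genomic loci."""

    name: str
    sequence: str
    loci: list[tuple[str, int, int]] = field(default_factory=list)  # (chrom, start, end)

    def __post_init__(self) -> None:
        if not 20 <= len(self.sequence) <= 24:
            raise ValueError(
                f"mature miRNA {self.name!r}: length {len(self.sequence)} outside 20-24 nt")


@dataclass(frozen=True)
class FeatureExpression:
    feature_id: str
    sample_id: str
    raw_count: int
    rpm: float


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def match_conserved(read: str, mature: str,
                    max_mismatches: int = MAX_MISMATCHES) -> tuple[bool, int]:
    """Ungapped comparison with the conserved-miRNA rule (<= 2 mismatches).

    Equal lengths compare position-wise (Hamming). Unequal lengths slide the
    shorter sequence over the longer one and take the best offset; overhangs
    are not counted as mismatches.
    """
    short, long_ = sorted((read.upper(), mature.upper()), key=len)
    best = len(short) + 1
    for offset in range(len(long_) - len(short) + 1):
        d = _hamming(short, long_[offset : offset + len(short)])
        if d < best:
            best = d
            if best == 0:
                break
    return best <= max_mismatches, best


def locate_mirnas(mature_ref: Mapping[str, str],
                  index: ExactIndex | Genome) -> list[MatureMiRNA]:
    """Resolve each reference mature sequence to its exact genomic loci."""
    if isinstance(index, Genome):
        index = ExactIndex(index)
    out = []
    for name, seq in mature_ref.items():
        loci = [(chrom, start, start + len(seq))
                for chrom, start, _strand in index.find(seq.upper())]
        out.append(MatureMiRNA(name, seq.upper(), sorted(set(loci))))
    return out


def _seq_matrix(seqs: list[str]) -> "np.ndarray":
    return np.frombuffer("".join(seqs).encode(), dtype=np.uint8).reshape(len(seqs), -1)


def identify_conserved(reads: Sequence[SmallRNARead],
                       mature_ref: Mapping[str, str],
                       max_mismatches: int = MAX_MISMATCHES) -> dict[str, int]:
    """Reference miRNAs supported by >=1 clean read at <= max_mismatches.

    Returns miRNA name -> total read count matching it (expression-free
    evidence of conservation, not locus-based quantification). Matching is the
    :func:`match_conserved` rule, evaluated in bulk: reads are grouped by
    length and compared position-wise over every ungapped offset.
    """
    by_len: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for length in {len(r.sequence) for r in reads}:
        group = [r for r in reads if len(r.sequence) == length]
        by_len[length] = (_seq_matrix([r.sequence for r in group]),
                          np.array([r.count for r in group]))
    support: dict[str, int] = {}
    for name, mseq in mature_ref.items():
        mseq = mseq.upper()
        m_arr = np.frombuffer(mseq.encode(), dtype=np.uint8)
        total = 0
        for length, (matrix, counts) in by_len.items():
            best = np.full(len(counts), length + 1)
            if length <= len(mseq):
                for off in range(len(mseq) - length + 1):
                    d = (matrix != m_arr[off:off + length]).sum(axis=1)
                    np.minimum(best, d, out=best)
            else:
                for off in range(length - len(mseq) + 1):
                    d = (matrix[:, off:off + len(mseq)] != m_arr).sum(axis=1)
                    np.minimum(best, d, out=best)
            total += int(counts[best <= max_mismatches].sum())
        if total:
            support[name] = total
    return support


def count_mirna_reads(hits: Sequence[AlignmentHit],
                      mirnas: Sequence[MatureMiRNA],
                      read_counts: Mapping[str, int],
                      unique_only: bool = False) -> dict[str, int]:
    """Raw miRNA counts by >= 1 nt genomic overlap with any mature locus.

    A distinct read contributes its collapse count to every miRNA whose locus
    any of its placements overlaps (a read spanning two distinct miRNAs counts
    for both). miRNAs with no genomic locus are skipped with a warning.
    """
    loci_by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    counts: dict[str, int] = {}
    for m in mirnas:
        if not m.loci:
            warnings.warn(f"miRNA {m.name} has no genomic locus; excluded", stacklevel=2)
            continue
        counts[m.name] = 0
        for chrom, start, end in m.loci:
            loci_by_chrom.setdefault(chrom, []).append((start, end, m.name))
    for chrom in loci_by_chrom:
        loci_by_chrom[chrom].sort()

    assigned: dict[str, set[str]] = {}
    for h in hits:
        if unique_only and not h.unique:
            continue
        loci = loci_by_chrom.get(h.chrom)
        if not loci:
            continue
        for start, end, name in loci:
            if start >= h.end:
                break
            if end > h.start:  # >= 1 nt overlap
                assigned.setdefault(h.read, set()).add(name)
    for read, names in assigned.items():
        for name in names:
            counts[name] += read_counts[read]
    return counts


def mirna_assigned_reads(hits: Sequence[AlignmentHit],
                         mirnas: Sequence[MatureMiRNA]) -> set[str]:
    """Read sequences counted to any miRNA (to exclude from siRNA analysis)."""
    loci_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for m in mirnas:
        for chrom, start, end in m.loci:
            loci_by_chrom.setdefault(chrom, []).append((start, end))
    for chrom in loci_by_chrom:
        loci_by_chrom[chrom].sort()
    out: set[str] = set()
    for h in hits:
        for start, end in loci_by_chrom.get(h.chrom, ()):
            if start >= h.end:
                break
            if end > h.start:
                out.add(h.read)
                break
    return out


def rpm_normalize(raw: float, clean_total: int) -> float:
    """RPM = raw count / total clean reads x 10^6."""
    if clean_total <= 0:
        raise ValueError("clean_total must be positive for RPM normalisation")
    return raw / clean_total * 1_000_000.0
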