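"""Zero-mismatch placement of clean reads on a genome.

Parent 1 reads are placed on subgenome A, parent 2 reads on subgenome C, and
allopolyploid (F2) reads on the merged A+C genome. The matcher is exact: a hit
is a full-length, mismatch-free occurrence of the read on either strand, found
via a seed index of fixed-length k-mers with full verification. Uniqueness
(exactly one hit genome-wide, both strands pooled) is tracked per read because
downstream siRNA quantification is restricted to uniquely mapped reads.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Sequence

from ._seq import read_fasta, revcomp
from .preprocess import SmallRNARead


@dataclass
class Genome:
    """Ordered chromosome set with a subgenome label per chromosome."""

    chromosomes: dict[str, str]
    subgenome: dict[str, str]

    def __post_init__(self) -> None:
        if set(self.chromosomes) != set(self.subgenome):
            raise ValueError("subgenome labels must cover exactly the chromosome set")

    @classmethod
    def from_fasta(cls, path: str | os.PathLike, label: str) -> "Genome":
        chroms = read_fasta(path)
        return cls(chroms, {name: label for name in chroms})

    @classmethod
    def merge(cls, genome_a: "Genome", genome_c: "Genome") -> "Genome":
        """Merged allopolyploid reference; chromosomes prefixed 'A_'/'C_'."""
        chroms: dict[str, str] = {}
        labels: dict[str, str] = {}
        for prefix, g in (("A", genome_a), ("C", genome_c)):
            for name, seq in g.chromosomes.items():
                chroms[f"{prefix}_{name}"] = seq
                labels[f"{prefix}_{name}"] = prefix
        return cls(chroms, labels)

    def __len__(self) -> int:
        return sum(len(s) for s in self.chromosomes.values())


@dataclass(frozen=True)
class AlignmentHit:
    """A zero-mismatch placement: genome[start:end] (strand-adjusted) == read."""

    read: str
    chrom: str
    start: int          # 0-based
    end: int            # exclusive
    strand: str         # '+' or '-'
    unique: bool


class ExactIndex:
    """Exact substring locator over both strands, for 18-30 nt queries.

    Seeds of ``seed_len`` nt index the forward strand; queries are verified to
    full length. Minus-strand hits are found by locating the query's reverse
    complement on the forward strand.
    """

    def __init__(self, genome: Genome, seed_len: int = 18):
        if len(genome) == 0:
            raise ValueError("cannot index an empty genome")
        self.genome = genome
        self.seed_len = seed_len
        self._seeds: dict[str, list[tuple[str, int]]] = {}
        for chrom, seq in genome.chromosomes.items():
            for i in range(0, len(seq) - seed_len + 1):
                self._seeds.setdefault(seq[i : i + seed_len], []).append((chrom, i))

    def _forward_occurrences(self, pattern: str) -> list[tuple[str, int]]:
        k = self.seed_len
        if len(pattern) < k:
            # short queries fall back to a direct scan
            return [(chrom, i)
                    for chrom, seq in self.genome.chromosomes.items()
                    for i in _find_all(seq, pattern)]
        out = []
        for chrom, i in self._seeds.get(pattern[:k], ()):
            seq = self.genome.chromosomes[chrom]
            if seq[i : i + len(pattern)] == pattern:
                out.append((chrom, i))
        return out

    def find(self, pattern: str) -> list[tuple[str, int, str]]:
        """All (chrom, start, strand) occurrences of pattern on either strand."""
        hits = [(c, i, "+") for c, i in self._forward_occurrences(pattern)]
        rc = revcomp(pattern)
        hits += [(c, i, "-") for c, i in self._forward_occurrences(rc)]
        return sorted(hits)


def _find_all(haystack: str, needle: str) -> Iterable[int]:
    i = haystack.find(needle)
    while i != -1:
        yield i
        i = haystack.find(needle, i + 1)


def scan_hits(genome: Genome, pattern: str) -> list[tuple[str, int, str]]:
    """Brute-force two-strand scan; the reference behaviour for ExactIndex."""
    hits = [(chrom, i, "+")
            for chrom, seq in genome.chromosomes.items()
            for i in _find_all(seq, pattern)]
    rc = revcomp(pattern)
    hits += [(chrom, i, "-")
             for chrom, seq in genome.chromosomes.items()
             for i in _find_all(seq, rc)]
    return sorted(hits)


def align_reads(reads: Sequence[SmallRNARead],
                genome: Genome | ExactIndex) -> tuple[list[AlignmentHit], float]:
    """Place collapsed reads; returns (hits, mapping rate).

    Every zero-mismatch placement is reported. A read is `unique` iff it has
    exactly one placement genome-wide. The mapping rate weights each distinct
    read by its collapse count over the clean total.
    """
    index = genome if isinstance(genome, ExactIndex) else ExactIndex(genome)
    hits: list[AlignmentHit] = []
    mapped_mass = 0
    total_mass = 0
    for read in reads:
        total_mass += read.count
        occ = index.find(read.sequence)
        if not occ:
            continue
        mapped_mass += read.count
        unique = len(occ) == 1
        for chrom, start, strand in occ:
            hits.append(AlignmentHit(read.sequence, chrom, start,
                                     start + len(read.sequence), strand, unique))
    rate = mapped_mass / total_mass if total_mass else 0.0
    return hits, rate


def hits_to_tsv(hits: Sequence[AlignmentHit], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("read\tchrom\tstart\tend\tstrand\tunique\n")
        for h in hits:
            fh.write(f"{h.read}\t{h.chrom}\t{h.start}\t{h.end}\t{h.strand}\t{int(h.unique)}\n")


def hits_to_sam(hits: Sequence[AlignmentHit], genome: Genome,
                path: str | os.PathLike) -> None:
    """Minimal SAM export of mapped placements (unmapped reads omitted)."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for chrom, seq in genome.chromosomes.items():
            fh.write(f"@SQ\tSN:{chrom}\tLN:{len(seq)}\n")
        for i, h in enumerate(hits):
            flag = 16 if h.strand == "-" else 0
            seq = h.read if h.strand == "+" else revcomp(h.read)
            fh.write(f"read{i}\t{flag}\t{h.chrom}\t{h.start + 1}\t"
                     f"{255 if h.unique else 0}\t{len(h.read)}M\t*\t0\t0\t{seq}\t*\n")


def hits_from_sam(path: str | os.PathLike) -> list[AlignmentHit]:
    """Import placements from bowtie-style SAM (perfect, full-length matches).

    Uniqueness is recomputed from hit multiplicity per read sequence.
    """
    raw: list[tuple[str, str, int, str]] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("@"):
                continue
            fields = line.rstrip("\n").split("\t")
            flag = int(fields[1])
            if flag & 4:
                continue
            chrom, pos, seq = fields[2], int(fields[3]) - 1, fields[9].upper()
            if flag & 16:
                strand, read = "-", revcomp(seq)
            else:
                strand, read = "+", seq
            raw.append((read, chrom, pos, strand))
    from collections import Counter
    multiplicity = Counter(read for read, *_ in raw)
    return [AlignmentHit(read, chrom, pos, pos + len(read), strand,
                         multiplicity[read] == 1)
            for read, chrom, pos, strand in raw]
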