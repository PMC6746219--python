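"""siRNA cluster calling and quantification.

A siRNA cluster is a genomic region matched by at least three uniquely mapped
non-miRNA small-RNA reads; clusters lying within 200 nt of one another are
merged and treated as a single cluster. Clusters are called on the pooled hits
of all samples (so every sample is quantified over the same intervals) and
quantified per sample from unique, full-length, zero-mismatch placements
overlapping the cluster.
"""

from __future__ import annotations

import os
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .align import AlignmentHit
from .mirna import rpm_normalize

MIN_READS = 3
MERGE_DIST = 200


@dataclass
class SiRNACluster:
    chrom: str
    start: int                # 0-based half-open
    end: int
    support: int              # pooled read count backing the call
    cluster_id: str = ""
    counts: dict[str, int] = field(default_factory=dict)   # sample -> raw count
    rpm: dict[str, float] = field(default_factory=dict)


def select_sirna_hits(hits: Sequence[AlignmentHit],
                      mirna_reads: set[str]) -> tuple[list[AlignmentHit], list[AlignmentHit]]:
    """Partition hits into (siRNA-eligible, excluded).

    Eligible hits belong to reads that were not counted to any miRNA and map
    to a unique locus.
    """
    kept, excluded = [], []
    for h in hits:
        (kept if h.unique and h.read not in mirna_reads else excluded).append(h)
    return kept, excluded


def _intervals(hits: Sequence[AlignmentHit],
               read_counts: Mapping[str, int]) -> list[tuple[str, int, int, int]]:
    return [(h.chrom, h.start, h.end, read_counts[h.read]) for h in hits]


def call_clusters(intervals: Sequence[tuple[str, int, int, int]],
                  min_reads: int = MIN_READS,
                  merge_dist: int = MERGE_DIST) -> list[SiRNACluster]:
    """Two-phase cluster calling over (chrom, start, end, count) read intervals.

    1. Seed clusters are connected components of *overlapping* read intervals.
    2. Components supported by >= min_reads reads (multiplicity-weighted)
       survive.
    3. Surviving clusters separated by a gap <= merge_dist are merged to a
       fixed point. Bounds are the min start / max end of member reads.
    """
    if merge_dist < 0:
        raise ValueError("merge_dist must be >= 0")
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")
    by_chrom: dict[str, list[tuple[int, int, int]]] = {}
    for chrom, start, end, count in intervals:
        if end <= start:
            raise ValueError(f"empty interval {chrom}:{start}-{end}")
        by_chrom.setdefault(chrom, []).append((start, end, count))

    out: list[SiRNACluster] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom])
        # phase 1+2: overlap components, multiplicity-weighted support filter
        seeds: list[tuple[int, int, int]] = []
        cur_start, cur_end, cur_support = ivs[0][0], ivs[0][1], ivs[0][2]
        for start, end, count in ivs[1:]:
            if start < cur_end:  # strict overlap
                cur_end = max(cur_end, end)
                cur_support += count
            else:
                seeds.append((cur_start, cur_end, cur_support))
                cur_start, cur_end, cur_support = start, end, count
        seeds.append((cur_start, cur_end, cur_support))
        surviving = [s for s in seeds if s[2] >= min_reads]
        # phase 3: merge surviving clusters with gap <= merge_dist
        merged: list[list[int]] = []
        for start, end, support in surviving:
            if merged and start - merged[-1][1] <= merge_dist:
                merged[-1][1] = max(merged[-1][1], end)
                merged[-1][2] += support
            else:
                merged.append([start, end, support])
        out.extend(SiRNACluster(chrom, s, e, sup) for s, e, sup in merged)
    for i, c in enumerate(out, 1):
        c.cluster_id = f"cluster{i:05d}"
    return out


def call_clusters_from_hits(hits: Sequence[AlignmentHit],
                            read_counts: Mapping[str, int],
                            min_reads: int = MIN_READS,
                            merge_dist: int = MERGE_DIST,
                            min_distinct: int | None = None) -> list[SiRNACluster]:
    """Cluster calling from alignment hits; optionally require a minimum number
    of *distinct* read sequences instead of total multiplicity."""
    if min_distinct is None:
        return call_clusters(_intervals(hits, read_counts), min_reads, merge_dist)
    # distinct-read thresholding: count each distinct sequence once for the
    # support filter, then restore multiplicity-weighted support afterwards
    distinct = call_clusters([(h.chrom, h.start, h.end, 1) for h in hits],
                             min_distinct, merge_dist)
    for c in distinct:
        c.support = sum(read_counts[h.read] for h in hits
                        if h.chrom == c.chrom and h.start < c.end and h.end > c.start)
    return distinct


def quantify_clusters(clusters: Sequence[SiRNACluster],
                      sample_hits: Mapping[str, Sequence[AlignmentHit]],
                      sample_read_counts: Mapping[str, Mapping[str, int]],
                      clean_totals: Mapping[str, int]) -> list[SiRNACluster]:
    """Per-sample raw counts and RPM for each cluster.

    Only unique, full-length zero-mismatch placements overlapping the cluster
    by >= 1 nt are counted (multiplicity-weighted). Output clusters are the
    input objects with counts/rpm filled in.
    """
    by_chrom: dict[str, list[SiRNACluster]] = {}
    for c in clusters:
        by_chrom.setdefault(c.chrom, []).append(c)
    starts = {chrom: [c.start for c in sorted(cs, key=lambda c: c.start)]
              for chrom, cs in by_chrom.items()}
    ordered = {chrom: sorted(cs, key=lambda c: c.start) for chrom, cs in by_chrom.items()}

    for c in clusters:
        for sample in sample_hits:
            c.counts[sample] = 0
    for sample, hits in sample_hits.items():
        counts = sample_read_counts[sample]
        for h in hits:
            if not h.unique:
                continue
            cs = ordered.get(h.chrom)
            if not cs:
                continue
            # clusters are disjoint (gaps > merge_dist); at most one overlaps
            i = bisect_right(starts[h.chrom], h.start) - 1
            for j in (i, i + 1):
                if 0 <= j < len(cs) and h.start < cs[j].end and h.end > cs[j].start:
                    cs[j].counts[sample] += counts[h.read]
    for c in clusters:
        c.rpm = {s: rpm_normalize(n, clean_totals[s]) for s, n in c.counts.items()}
    return list(clusters)


def clusters_to_bed(clusters: Sequence[SiRNACluster], path: str | os.PathLike) -> None:
    """BED6: name = cluster id, score = supporting read count."""
    with open(path, "w") as fh:
        for c in clusters:
            fh.write(f"{c.chrom}\t{c.start}\t{c.end}\t{c.cluster_id}\t{c.support}\t.\n")
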