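"""Independent reference implementations used to check the package.

These are deliberately naive (exhaustive enumeration, O(n*m) scans, direct
combinatorial sums) and share no code with the implementations they verify.
"""

from __future__ import annotations

import math


def brute_force_scan(chromosomes: dict[str, str], pattern: str,
                     revcomp) -> list[tuple[str, int, str]]:
    """All exact occurrences of pattern on both strands, by direct comparison."""
    hits = []
    for strand, query in (("+", pattern), ("-", revcomp(pattern))):
        for chrom, seq in chromosomes.items():
            for i in range(len(seq) - len(query) + 1):
                if seq[i : i + len(query)] == query:
                    hits.append((chrom, i, strand))
    return sorted(hits)


def exhaustive_cluster_call(intervals, min_reads=3, merge_dist=200):
    """Pairwise-merge-to-fixed-point cluster calling.

    Phase 1: merge any two strictly overlapping read intervals until no pair
    overlaps. Phase 2: drop components below min_reads. Phase 3: merge any two
    surviving clusters whose gap is <= merge_dist until fixed point.
    Returns sorted (chrom, start, end, support) tuples.
    """
    def merge_fixed_point(items, mergeable):
        items = list(items)
        changed = True
        while changed:
            changed = False
            for i in range(len(items)):
                for j in range(i + 1, len(items)):
                    a, b = items[i], items[j]
                    if a[0] == b[0] and mergeable(a, b):
                        merged = (a[0], min(a[1], b[1]), max(a[2], b[2]), a[3] + b[3])
                        items[i] = merged
                        del items[j]
                        changed = True
                        break
                if changed:
                    break
        return items

    overlap = lambda a, b: a[1] < b[2] and b[1] < a[2]
    components = merge_fixed_point(
        [(c, s, e, n) for c, s, e, n in intervals], overlap)
    surviving = [c for c in components if c[3] >= min_reads]
    gap_ok = lambda a, b: max(a[1], b[1]) - min(a[2], b[2]) <= merge_dist or overlap(a, b)
    return sorted(merge_fixed_point(surviving, gap_ok))


def mirna_overlap_counts(hits, loci_by_mirna, read_counts):
    """Direct enumeration of the >=1 nt overlap counting rule.

    hits: iterable of (read, chrom, start, end); loci_by_mirna: name ->
    [(chrom, start, end)]. A distinct read contributes its count to every
    miRNA at least one of whose loci at least one of its hits overlaps.
    """
    per_read_hits: dict[str, list] = {}
    for read, chrom, start, end in hits:
        per_read_hits.setdefault(read, []).append((chrom, start, end))
    counts = {name: 0 for name in loci_by_mirna}
    for read, placements in per_read_hits.items():
        for name, loci in loci_by_mirna.items():
            if any(c == lc and s < le and e > ls
                   for c, s, e in placements
                   for lc, ls, le in loci):
                counts[name] += read_counts[read]
    return counts


def bh_step_up(pvals):
    """Benjamini-Hochberg adjusted p-values by the direct step-up definition."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adjusted = [0.0] * m
    running_min = 1.0
    for rank_from_end in range(m, 0, -1):
        i = order[rank_from_end - 1]
        value = pvals[i] * m / rank_from_end
        running_min = min(running_min, value)
        adjusted[i] = min(running_min, 1.0)
    return adjusted


def hypergeom_upper_tail(k, n, K, N):
    """P(X >= k) by direct summation of the hypergeometric mass."""
    total = 0.0
    for x in range(k, min(n, K) + 1):
        total += math.comb(K, x) * math.comb(N - K, n - x) / math.comb(N, n)
    return min(total, 1.0)


def two_sided_normal_p(z):
    """Two-sided standard-normal p-value via erfc, independent of scipy."""
    return math.erfc(abs(z) / math.sqrt(2.0))


def score_all_windows(mirna, site_scorer, transcript):
    """Enumerate every window score independently of the scanner."""
    L = len(mirna)
    return [(start, site_scorer(mirna, transcript[start:start + L]))
            for start in range(len(transcript) - L + 1)]
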