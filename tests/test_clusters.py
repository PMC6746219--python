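import numpy as np
import pytest

from allosrna.align import AlignmentHit
from allosrna.clusters import (SiRNACluster, call_clusters,
                               call_clusters_from_hits, quantify_clusters,
                               select_sirna_hits)
from oracles import exhaustive_cluster_call


def iv(start, end, count=1, chrom="chr1"):
    return (chrom, start, end, count)


def spans(clusters):
    return sorted((c.chrom, c.start, c.end, c.support) for c in clusters)


class TestCallClusters:
    def test_three_overlapping_reads_form_cluster(self):
        got = call_clusters([iv(100, 121), iv(110, 131), iv(105, 128)])
        assert spans(got) == [("chr1", 100, 131, 3)]

    def test_two_reads_below_threshold(self):
        assert call_clusters([iv(100, 121), iv(110, 131)]) == []

    def test_three_identical_reads_qualify_by_multiplicity(self):
        got = call_clusters([iv(100, 121, count=3)])
        assert spans(got) == [("chr1", 100, 121, 3)]

    def test_min_distinct_alternative(self):
        hits = [AlignmentHit("AAA", "chr1", 100, 121, "+", True)]
        assert call_clusters_from_hits(hits, {"AAA": 3}, min_distinct=3) == []
        got = call_clusters_from_hits(hits, {"AAA": 3}, min_distinct=1)
        assert spans(got) == [("chr1", 100, 121, 3)]

    @pytest.mark.parametrize("gap,n_expected", [(150, 1), (200, 1), (201, 2), (250, 2)])
    def test_merge_distance_boundary(self, gap, n_expected):
        block1 = [iv(0, 21), iv(0, 21), iv(0, 21)]
        start2 = 21 + gap
        block2 = [iv(start2, start2 + 21, count=3)]
        got = call_clusters(block1 + block2)
        assert len(got) == n_expected

    def test_weak_neighbor_dropped_before_merge(self):
        # 2-read component between two strong ones must not rescue itself
        reads = ([iv(0, 24, count=3)] + [iv(100, 124)] * 2 + [iv(500, 524, count=3)])
        got = call_clusters(reads)
        assert spans(got) == [("chr1", 0, 24, 3), ("chr1", 500, 524, 3)]

    def test_negative_merge_dist_rejected(self):
        with pytest.raises(ValueError, match="merge_dist"):
            call_clusters([iv(0, 21, count=3)], merge_dist=-1)

    def test_order_invariance(self, rng):
        reads = [iv(int(s), int(s) + 22, int(c))
                 for s, c in zip(rng.integers(0, 3000, 60), rng.integers(1, 4, 60))]
        ref = spans(call_clusters(reads))
        for _ in range(3):
            perm = [reads[i] for i in rng.permutation(len(reads))]
            assert spans(call_clusters(perm)) == ref

    def test_output_gaps_exceed_merge_distance(self, rng):
        reads = [iv(int(s), int(s) + 24) for s in rng.integers(0, 5000, 300)]
        got = sorted(call_clusters(reads), key=lambda c: c.start)
        for a, b in zip(got, got[1:]):
            assert b.start - a.end > 200

    def test_min_reads_monotone_containment(self, rng):
        # a stricter support threshold can only lose cluster territory: every
        # cluster at min_reads=k is contained in one at any lower threshold
        # (the post-merge cluster COUNT itself is not monotone: dropping a weak
        # bridge component can split one merged cluster into two)
        reads = [iv(int(s), int(s) + 22, int(c))
                 for s, c in zip(rng.integers(0, 4000, 100), rng.integers(1, 5, 100))]
        tiers = [call_clusters(reads, min_reads=k) for k in (1, 3, 5, 8)]
        for loose, strict in zip(tiers, tiers[1:]):
            for c in strict:
                assert any(u.chrom == c.chrom and u.start <= c.start
                           and u.end >= c.end for u in loose)
            assert (sum(c.support for c in strict)
                    <= sum(c.support for c in loose))

    def test_monotone_under_added_reads(self, rng):
        a = [iv(int(s), int(s) + 21) for s in rng.integers(0, 3000, 80)]
        b = [iv(int(s), int(s) + 21) for s in rng.integers(0, 3000, 40)]
        from_a = call_clusters(a)
        from_union = call_clusters(a + b)
        for c in from_a:
            assert any(u.start <= c.start and u.end >= c.end and u.chrom == c.chrom
                       for u in from_union)

    def test_matches_exhaustive_pairwise_merge(self, rng):
        for _ in range(30):
            n = int(rng.integers(5, 120))
            starts = rng.integers(0, 8000, size=n)
            lengths = rng.integers(18, 31, size=n)
            counts = rng.integers(1, 4, size=n)
            chroms = rng.choice(["chr1", "chr2"], size=n)
            reads = [(c, int(s), int(s + l), int(m))
                     for c, s, l, m in zip(chroms, starts, lengths, counts)]
            assert spans(call_clusters(reads)) == exhaustive_cluster_call(reads)


class TestSelectSirnaHits:
    def hit(self, read, unique=True):
        return AlignmentHit(read, "chr1", 0, 21, "+", unique)

    def test_partition(self):
        hits = [self.hit("a"), self.hit("b", unique=False), self.hit("c")]
        kept, excluded = select_sirna_hits(hits, {"c"})
        assert [h.read for h in kept] == ["a"]
        assert {h.read for h in excluded} == {"b", "c"}
        assert len(kept) + len(excluded) == len(hits)


class TestQuantify:
    def cluster(self):
        return SiRNACluster("chr1", 1000, 1400, support=5, cluster_id="cl1")

    def test_overlapping_unique_reads_counted(self):
        c = self.cluster()
        hits = {"s1": [AlignmentHit("in", "chr1", 1100, 1121, "+", True),
                       AlignmentHit("edge", "chr1", 990, 1011, "+", True),
                       AlignmentHit("multi", "chr1", 1200, 1221, "+", False),
                       AlignmentHit("out", "chr1", 2000, 2021, "+", True)]}
        counts = {"s1": {"in": 2, "edge": 1, "multi": 10, "out": 1}}
        quantify_clusters([c], hits, counts, {"s1": 1_000_000})
        assert c.counts["s1"] == 3          # 'in' fully inside + 'edge' 11-nt overlap
        assert c.rpm["s1"] == pytest.approx(3.0)

    def test_totals_match_brute_force_recount(self, rng):
        reads = {f"r{i}": int(c) for i, c in enumerate(rng.integers(1, 6, 200))}
        hits = [AlignmentHit(r, "chr1", int(s), int(s) + 21, "+", True)
                for r, s in zip(reads, rng.integers(0, 6000, 200))]
        clusters = call_clusters([(h.chrom, h.start, h.end, reads[h.read])
                                  for h in hits])
        quantify_clusters(clusters, {"s": hits}, {"s": reads}, {"s": 10_000})
        for c in clusters:
            expected = sum(reads[h.read] for h in hits
                           if h.start < c.end and h.end > c.start)
            assert c.counts["s"] == expected
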