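import warnings

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from allosrna.preprocess import (StructuralFilter, clean_library, collapse,
                                 filter_reads, remove_structural, trim_adapters)
from allosrna._seq import revcomp

ADAPTER3 = "TGGAATTC"
INSERT = "ACGTACGTACGTACGTACGTA"

reads_strategy = st.lists(
    st.text(alphabet="ACGT", min_size=10, max_size=40), max_size=60)


class TestTrimAdapters:
    def test_full_adapter_removed(self):
        assert trim_adapters(INSERT + ADAPTER3, ADAPTER3) == INSERT

    def test_partial_adapter_prefix_removed(self):
        assert trim_adapters(INSERT + ADAPTER3[:6], ADAPTER3) == INSERT

    def test_no_sufficient_overlap_unchanged(self):
        read = INSERT + ADAPTER3[:5]  # below the 6-nt minimum overlap
        assert trim_adapters(read, ADAPTER3) == read

    def test_read_equal_to_adapter_removed(self):
        assert trim_adapters(ADAPTER3, ADAPTER3) is None

    def test_five_prime_rule_symmetric(self):
        adapter5 = "GTTCAGAGTT"
        assert trim_adapters(adapter5[-7:] + INSERT, None, adapter5) == INSERT

    def test_longest_match_wins(self):
        # suffix matches both a 6-nt and a full-length adapter prefix
        read = INSERT + ADAPTER3
        assert trim_adapters(read, ADAPTER3, min_overlap=6) == INSERT

    def test_non_nucleotide_rejected(self):
        with pytest.raises(ValueError, match="non-ACGTN"):
            trim_adapters("ACGTXACGT", ADAPTER3)


class TestFilterReads:
    def test_boundaries_inclusive(self):
        reads = ["A" * 17, "C" * 18, "G" * 30, "T" * 31]
        assert filter_reads(reads) == ["C" * 18, "G" * 30]

    def test_n_containing_removed(self):
        assert filter_reads(["ACGN" + "A" * 17]) == []

    def test_empty_input(self):
        assert filter_reads([]) == []

    @settings(max_examples=50, deadline=None)
    @given(reads_strategy)
    def test_idempotent(self, reads):
        once = filter_reads(reads)
        assert filter_reads(once) == once


class TestRemoveStructural:
    structural = {"rRNA": "ACGTACGTAAATTTCCCGGGACGTACGTACGTAAGGTCAGTTA"}

    def test_substring_removed(self):
        read = self.structural["rRNA"][5:30]
        kept, removed = remove_structural([read], self.structural)
        assert kept == [] and removed == 1

    def test_reverse_complement_removed(self):
        read = revcomp(self.structural["rRNA"][10:34])
        kept, removed = remove_structural([read], self.structural)
        assert kept == [] and removed == 1

    def test_conservation(self):
        reads = [self.structural["rRNA"][:20], "T" * 20, "A" * 20]
        kept, removed = remove_structural(reads, self.structural)
        assert len(kept) + removed == len(reads)

    def test_empty_reference_warns_and_keeps(self):
        with pytest.warns(UserWarning, match="empty structural"):
            kept, removed = remove_structural(["A" * 20], {})
        assert kept == ["A" * 20] and removed == 0

    def test_idempotent(self):
        reads = [self.structural["rRNA"][:21], "TGCA" * 5]
        filt = StructuralFilter(self.structural)
        once, _ = remove_structural(reads, filt)
        twice, n = remove_structural(once, filt)
        assert twice == once and n == 0


class TestCollapse:
    def test_multiplicities(self):
        reads = ["ACG" * 7, "ACG" * 7, "TGC" * 7]
        records = collapse(reads)
        assert {(r.sequence, r.count) for r in records} == {("ACG" * 7, 2),
                                                            ("TGC" * 7, 1)}

    def test_all_distinct(self):
        records = collapse(["ACGT" * 5, "TGCA" * 5])
        assert all(r.count == 1 for r in records)

    @settings(max_examples=50, deadline=None)
    @given(reads_strategy)
    def test_counts_conserve_input_size(self, reads):
        assert sum(r.count for r in collapse(reads)) == len(reads)


def test_clean_library_stage_conservation():
    structural = {"rRNA": "AGTCCATGACCTTAGCAAGGTCAGTTAGCATTACGGATCAAT"}
    raw = [
        "ACGTACGTACGTACGTACGTA" + ADAPTER3,      # clean 21-mer
        structural["rRNA"][5:28] + ADAPTER3,     # structural contaminant
        "ACGTACGTAC" + ADAPTER3,                 # too short after trimming
        ADAPTER3,                                # pure adapter
        "ACGTACGTACGTACGTACGTA" + ADAPTER3,      # duplicate of the first
    ]
    collapsed, stats = clean_library(raw, ADAPTER3, structural=structural)
    assert stats.total_raw == 5
    assert (stats.trimmed_away + stats.length_filtered
            + stats.structural_removed + stats.clean) == stats.total_raw
    assert sum(stats.length_histogram.values()) == stats.clean
    assert sum(r.count for r in collapsed) == stats.clean
    assert stats.clean == 2 and collapsed[0].count == 2


@settings(max_examples=30, deadline=None)
@given(reads_strategy)
def test_clean_library_conservation_property(reads):
    raw = [r + ADAPTER3 for r in reads]
    _, stats = clean_library(raw, ADAPTER3, structural={"s": "ACGTAGCTAGCTAAGCTAGCTA"})
    assert (stats.trimmed_away + stats.length_filtered
            + stats.structural_removed + stats.clean) == stats.total_raw
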