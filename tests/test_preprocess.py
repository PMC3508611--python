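"""Read cleaning, tag collapsing, length histogram and genome matching."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirskin.formats import RawRead, ReferenceSet
from mirskin.preprocess import (
    LibrarySummary,
    SequenceTag,
    clean_reads,
    collapse_tags,
    length_distribution,
    match_genome,
    percent,
)
from mirskin.seqindex import SubstringIndex, naive_match, revcomp

ADAPTER3 = "TGGAATTCTCGGGTGCCAAGG"
INSERT22 = "ACGTACGTGGCCATTACGTGCA"


def _read(seq, qual=None, rid="r"):
    return RawRead(rid, seq, qual if qual is not None else "I" * len(seq))


class TestCleanReads:
    def test_planted_insert_plus_full_adapter_is_recovered(self):
        assert clean_reads([_read(INSERT22 + ADAPTER3)], ADAPTER3) == [INSERT22]

    def test_partial_terminal_adapter_still_trims(self):
        # only 8 nt of adapter fit at the read end
        assert clean_reads([_read(INSERT22 + ADAPTER3[:8])], ADAPTER3) == [INSERT22]

    def test_17nt_insert_dropped_as_too_short(self):
        assert clean_reads([_read(INSERT22[:17] + ADAPTER3)], ADAPTER3) == []
        assert clean_reads([_read(INSERT22[:18] + ADAPTER3)], ADAPTER3) == [INSERT22[:18]]

    def test_read_without_adapter_seed_is_dropped(self):
        # insert presumed longer than the read, i.e. > 30 nt
        assert clean_reads([_read("ACGT" * 9)], ADAPTER3) == []

    def test_n_containing_read_dropped(self):
        assert clean_reads([_read(INSERT22[:10] + "N" + INSERT22[11:] + ADAPTER3)], ADAPTER3) == []

    def test_low_quality_base_dropped_when_qualities_present(self):
        seq = INSERT22 + ADAPTER3
        qual = "I" * 5 + "#" + "I" * (len(seq) - 6)  # '#' = Phred 2
        assert clean_reads([_read(seq, qual)], ADAPTER3) == []
        # pass-through when qualities absent
        assert clean_reads([RawRead("r", seq, None)], ADAPTER3) == [INSERT22]

    def test_five_prime_adapter_contaminant_discarded(self):
        adapter5 = "GTTCAGAGTTCTACAGTCCGACGATC"
        seq = adapter5 + INSERT22 + ADAPTER3
        assert clean_reads([_read(seq)], ADAPTER3, adapter5=adapter5) == []

    def test_empty_adapter_rejected(self):
        with pytest.raises(ValueError):
            clean_reads([], "")


class TestCollapseTags:
    def test_counts_per_distinct_sequence(self):
        tags = collapse_tags({"w": ["A" * 20] * 3 + ["T" * 20]})
        by_seq = {t.sequence: t.counts for t in tags}
        assert by_seq == {"A" * 20: {"w": 3}, "T" * 20: {"w": 1}}

    def test_shared_sequence_yields_one_tag_with_two_counts(self):
        tags = collapse_tags({"w": ["A" * 20], "b": ["A" * 20, "A" * 20]})
        assert len(tags) == 1
        assert tags[0].counts == {"w": 1, "b": 2}

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.text(alphabet="ACGT", min_size=18, max_size=25), max_size=60
        ),
        st.lists(
            st.text(alphabet="ACGT", min_size=18, max_size=25), max_size=60
        ),
    )
    def test_counts_conserve_clean_read_totals(self, lib_a, lib_b):
        tags = collapse_tags({"a": lib_a, "b": lib_b})
        assert sum(t.counts["a"] for t in tags) == len(lib_a)
        assert sum(t.counts["b"] for t in tags) == len(lib_b)

    def test_collapse_is_input_order_independent(self):
        seqs = ["ACGT" * 5, "TTTT" * 5, "ACGT" * 5, "GGCC" * 5]
        assert collapse_tags({"w": seqs}) == collapse_tags({"w": seqs[::-1]})


class TestLengthDistribution:
    def test_single_tag_weighted_by_read_count(self):
        hist = length_distribution([SequenceTag("A" * 22, {"w": 5})])
        assert hist[22] == 5
        assert sum(hist.values()) == 5
        assert set(hist) == set(range(18, 31))

    def test_permuting_tags_leaves_histogram_unchanged(self):
        tags = [
            SequenceTag("A" * 20, {"w": 3}),
            SequenceTag("C" * 22, {"w": 9}),
            SequenceTag("G" * 24, {"w": 1}),
        ]
        assert length_distribution(tags) == length_distribution(tags[::-1])

    def test_synthetic_libraries_are_dominated_by_22mers(self, sim_tags):
        hist = length_distribution(sim_tags)
        assert max(hist, key=hist.get) == 22


class TestMatchGenome:
    def test_tag_equal_to_genome_substring_matches(self):
        genome = ReferenceSet("genome", [("chr1", "TTTT" + INSERT22 + "GGGG")])
        matched, n, pct = match_genome(
            [SequenceTag(INSERT22, {"w": 4})], genome
        )
        assert matched == {INSERT22} and n == 4 and pct == 100.0

    def test_reverse_complement_counts_as_match(self):
        genome = ReferenceSet("genome", [("chr1", "TT" + revcomp(INSERT22) + "AA")])
        matched, _, _ = match_genome([SequenceTag(INSERT22, {"w": 1})], genome)
        assert matched == {INSERT22}

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_index_agrees_with_naive_scan(self, seed):
        rng = random.Random(seed)
        genome_seq = "".join(rng.choice("ACGT") for _ in range(300))
        records = [("g", genome_seq)]
        tags = []
        for _ in range(10):
            if rng.random() < 0.5:
                s = rng.randrange(0, 280)
                tags.append(genome_seq[s : s + 20])
            else:
                tags.append("".join(rng.choice("ACGT") for _ in range(20)))
        index = SubstringIndex(records, {20})
        for t in tags:
            assert (t in index) == naive_match(t, records, 0)

    def test_mismatch_tolerant_matching(self):
        genome = ReferenceSet("genome", [("chr1", "TTTT" + INSERT22 + "GGGG")])
        mutated = "G" + INSERT22[1:]
        matched0, _, _ = match_genome([SequenceTag(mutated, {"w": 1})], genome, 0)
        matched1, _, _ = match_genome([SequenceTag(mutated, {"w": 1})], genome, 1)
        assert matched0 == set() and matched1 == {mutated}


class TestAccounting:
    def test_percent_rounds_to_two_decimals(self):
        assert percent(1, 3) == 33.33

    def test_summary_invariants_enforced(self):
        with pytest.raises(ValueError):
            LibrarySummary("w", raw_reads=10, clean_reads=11, unique_tags=1)
        with pytest.raises(ValueError):
            LibrarySummary(
                "w", raw_reads=10, clean_reads=5, unique_tags=1,
                genome_matched_reads=6,
            )

    def test_raw_equals_clean_plus_dropped_on_synthetic_library(
        self, sim_reads, sim_clean, sim_config
    ):
        for lib in sim_reads:
            dropped = len(sim_reads[lib]) - len(sim_clean[lib])
            assert dropped >= 0
            assert len(sim_clean[lib]) + dropped == len(sim_reads[lib])
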