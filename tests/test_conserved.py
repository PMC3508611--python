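"""Conserved-miRNA matching, family grouping, isomiRs and arm usage."""

import random

import pytest

from mirskin.conserved import (
    align_ungapped,
    detect_arm_switch,
    end_heterogeneity,
    family_name,
    group_families,
    match_conserved,
    mirna_count_table,
)
from mirskin.fold import fold_rna
from mirskin.formats import ReferenceSet
from mirskin.preprocess import SequenceTag

MATURE = "ACGTACGTGGCCATTACGTGCA"  # 22 nt


def _catalog(entries):
    return ReferenceSet("known_mirna_mature", entries)


def _mutate(seq, positions):
    out = list(seq)
    for p in positions:
        out[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[p]]
    return "".join(out)


class TestMatchConserved:
    def test_identical_tag_hits_with_zero_mismatches(self):
        hits = match_conserved(
            [SequenceTag(MATURE, {"w": 1})], _catalog([("mir-1", MATURE)])
        )
        assert len(hits) == 1
        assert hits[0].mismatches == 0 and hits[0].identity == 1.0

    def test_three_substitutions_fail_both_rules(self):
        tag = _mutate(MATURE, [3, 9, 15])  # identity 19/22 < 0.9
        hits = match_conserved(
            [SequenceTag(tag, {"w": 1})], _catalog([("mir-1", MATURE)])
        )
        assert hits == []

    def test_two_mismatch_isomirs_are_recovered(self):
        tags = [
            SequenceTag(_mutate(MATURE, [5]), {"w": 1}),
            SequenceTag(_mutate(MATURE, [5, 18]), {"w": 1}),
            SequenceTag("GT" + MATURE + "A", {"w": 1}),  # end extension
        ]
        hits = match_conserved(tags, _catalog([("mir-1", MATURE)]))
        assert len(hits) == 3
        assert {h.mirna_id for h in hits} == {"mir-1"}

    def test_identity_over_90pct_needs_at_least_20_of_22_matches(self):
        mm2, ident2 = align_ungapped(_mutate(MATURE, [1, 2]), MATURE)
        mm3, ident3 = align_ungapped(_mutate(MATURE, [1, 2, 3]), MATURE)
        assert mm2 == 2 and ident2 > 0.90
        assert mm3 == 3 and not ident3 > 0.90

    def test_best_hit_ties_resolve_to_smallest_id(self):
        hits = match_conserved(
            [SequenceTag(MATURE, {"w": 1})],
            _catalog([("mir-b", MATURE), ("mir-a", MATURE)]),
        )
        assert hits[0].mirna_id == "mir-a"

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_seeded_matcher_equals_naive_matcher(self, seed):
        rng = random.Random(seed)
        catalog = _catalog(
            [
                (f"mir-{i}", "".join(rng.choice("ACGT") for _ in range(22)))
                for i in range(12)
            ]
        )
        tags = []
        for _ in range(80):
            if rng.random() < 0.5:
                base = rng.choice(catalog.records)[1]
                k = rng.randrange(4)
                tag = _mutate(base, rng.sample(range(22), k)) if k else base
            else:
                tag = "".join(rng.choice("ACGT") for _ in range(rng.randint(18, 26)))
            tags.append(SequenceTag(tag, {"w": 1}))
        naive = match_conserved(tags, catalog, algorithm="naive")
        seeded = match_conserved(tags, catalog, algorithm="seeded")
        key = lambda h: (h.tag.sequence, h.mirna_id, h.mismatches, h.identity)
        assert sorted(map(key, naive)) == sorted(map(key, seeded))

    def test_planted_catalog_tags_recovered_from_simulation(
        self, sim_data, sim_conserved_hits
    ):
        """Every non-arm-switched planted known miRNA is rediscovered."""
        expected = {
            p.id
            for p in sim_data.truth.planted_mirnas
            if p.kind == "known" and not p.arm_switched
        }
        found = {h.mirna_id for h in sim_conserved_hits}
        assert expected <= found


class TestFamilies:
    @pytest.mark.parametrize(
        "mirna_id,family",
        [
            ("let-7a", "let-7"),
            ("lpa-let-7i", "let-7"),
            ("miR-124a", "miR-124"),
            ("miR-124b", "miR-124"),
            ("hsa-miR-23b-3p", "miR-23"),
            ("miR-424*", "miR-424"),
            ("miR-154-2", "miR-154"),
        ],
    )
    def test_family_name_normalisation(self, mirna_id, family):
        assert family_name(mirna_id) == family

    def test_grouping_and_total_conservation(self):
        tags = [
            SequenceTag("A" * 22, {"w": 3, "b": 1}),
            SequenceTag("C" * 22, {"w": 2, "b": 0}),
            SequenceTag("G" * 22, {"w": 5, "b": 5}),
        ]
        hits = match_conserved(
            tags,
            _catalog([("let-7a", "A" * 22), ("let-7i", "C" * 22), ("miR-9", "G" * 22)]),
        )
        fams = group_families(hits)
        by_name = {f.family_name: f for f in fams}
        assert set(by_name) == {"let-7", "miR-9"}
        assert by_name["let-7"].member_ids == ["let-7a", "let-7i"]
        assert by_name["let-7"].total_reads == {"w": 5, "b": 1}
        # family totals conserve the per-hit totals
        assert sum(f.total_reads.get("w", 0) for f in fams) == sum(
            h.tag.counts["w"] for h in hits
        )

    def test_count_table_sums_tag_counts_per_mirna(self):
        tags = [
            SequenceTag(MATURE, {"w": 3, "b": 0}),
            SequenceTag(_mutate(MATURE, [4]), {"w": 2, "b": 7}),
        ]
        hits = match_conserved(tags, _catalog([("mir-1", MATURE)]))
        table = mirna_count_table(hits, ["w", "b"])
        assert table.counts["mir-1"] == {"w": 5, "b": 7}


PRECURSOR = (
    "GGACTG" + MATURE + "CTTATTATACAT"
    + "TGCACGTAATGGCCACGTACGT" + "CAGTCC"
)


class TestEndHeterogeneity:
    def test_reads_identical_to_mature_give_single_zero_offset_isoform(self):
        prof = end_heterogeneity(
            "pre-1", PRECURSOR, [SequenceTag(MATURE, {"w": 9})], MATURE
        )
        assert prof.isoforms == [(MATURE, 0, 0, 9)]
        assert prof.predominant == (MATURE, 0, 0, 9)
        assert prof.distinct_5p_ends == prof.distinct_3p_ends == 1

    def test_predominant_is_the_highest_count_isoform(self):
        plus1 = PRECURSOR[6 : 6 + 23]  # mature extended 1 nt at 3'
        prof = end_heterogeneity(
            "pre-1",
            PRECURSOR,
            [SequenceTag(MATURE, {"w": 3}), SequenceTag(plus1, {"w": 7})],
            MATURE,
        )
        assert prof.predominant == (plus1, 0, 1, 7)

    def test_missing_mature_is_an_error(self):
        with pytest.raises(ValueError, match="not found"):
            end_heterogeneity("pre-1", PRECURSOR, [], "T" * 22)

    def test_simulated_3prime_ends_vary_more_than_5prime(self, sim_data, sim_tags):
        """The generator trims/extends 3' ends more often than 5' ends;
        the isomiR profile of an abundant precursor must reflect it."""
        known = [
            p for p in sim_data.truth.planted_mirnas
            if p.kind == "known" and not p.arm_switched
        ]
        # most abundant planted miRNA: clearest isomiR cloud
        p = max(known, key=lambda q: q.proportions["white"])
        prof = end_heterogeneity(p.id, p.precursor, sim_tags, p.annotated_mature)
        assert prof.distinct_3p_ends > prof.distinct_5p_ends


class TestArmSwitch:
    def _fold(self):
        return fold_rna(PRECURSOR)

    def test_reads_on_opposite_arm_raise_switch_flag(self):
        star = PRECURSOR[40 : 40 + 22]
        usage = detect_arm_switch(
            "pre-1", PRECURSOR, self._fold(),
            [SequenceTag(star, {"w": 100})], annotated_arm="5p",
        )
        assert usage.dominant_arm == "3p" and usage.switched

    def test_equal_counts_tie_to_annotated_arm(self):
        star = PRECURSOR[40 : 40 + 22]
        usage = detect_arm_switch(
            "pre-1", PRECURSOR, self._fold(),
            [SequenceTag(MATURE, {"w": 5}), SequenceTag(star, {"w": 5})],
            annotated_arm="5p",
        )
        assert usage.dominant_arm == "5p" and not usage.switched

    def test_loop_only_reads_give_no_call(self):
        loop_read = PRECURSOR[28 : 28 + 18]
        assert (
            detect_arm_switch(
                "pre-1", PRECURSOR, self._fold(),
                [SequenceTag(loop_read, {"w": 3})], annotated_arm="5p",
            )
            is None
        )

    def test_planted_arm_switches_are_flagged(self, sim_data, sim_tags):
        switched = [p for p in sim_data.truth.planted_mirnas if p.arm_switched]
        assert switched, "generator must plant arm-switched precursors"
        for p in switched:
            fold = fold_rna(p.precursor)
            usage = detect_arm_switch(
                p.id, p.precursor, fold, sim_tags, annotated_arm=p.annotated_arm
            )
            assert usage is not None and usage.switched
            assert usage.dominant_arm == p.arm
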