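"""Novel-miRNA candidacy: criteria, MFEI arithmetic, set merging, and
recovery of planted precursors."""

import dataclasses
import math

import pytest

from mirskin.annotate import UNANNOTATED
from mirskin.fold import FoldResult, fold_rna
from mirskin.hairpin import (
    compute_mfei,
    evaluate_criteria,
    filter_mfei,
    merge_libraries,
    passing,
    predict_novel,
)
from mirskin.seqindex import revcomp

MATURE = "ACGTACGTGGCCATTACGTGCA"  # 22 nt
PRECURSOR = (
    "GGACTG" + MATURE + "CTTATTATACAT" + revcomp(MATURE) + "CAGTCC"
)
M0 = 6
M1 = M0 + 22


def _fold(mfe=None):
    fr = fold_rna(PRECURSOR)
    if mfe is not None:
        fr = dataclasses.replace(fr, mfe=mfe)
    return fr


class TestComputeMfei:
    def test_zero_mfe_gives_zero_mfei(self):
        amfe, mfei = compute_mfei(0.0, "ACGT" * 10)
        assert amfe == 0.0 and mfei == 0.0

    def test_direct_formula_evaluation(self):
        # 100 nt at exactly 50% GC, MFE -40: AMFE 40, MFEI 0.8
        seq = "AC" * 50
        amfe, mfei = compute_mfei(-40.0, seq)
        assert amfe == pytest.approx(40.0)
        assert mfei == pytest.approx(0.8)

    def test_hand_computed_mirna_scale_example(self):
        # 80 nt with 35 G+C (43.75%), MFE -34.83 (the average reported
        # for novel skin miRNAs): AMFE = 43.5375, MFEI = 0.99514...
        seq = "GC" * 17 + "G" + "AT" * 22 + "A"
        assert len(seq) == 80 and sum(c in "GC" for c in seq) == 35
        amfe, mfei = compute_mfei(-34.83, seq)
        assert amfe == pytest.approx(43.5375)
        assert mfei == pytest.approx(43.5375 / 43.75, abs=1e-9)

    def test_concatenation_linearity(self):
        seq = "ACGGTCAT" * 5
        _, mfei1 = compute_mfei(-17.3, seq)
        _, mfei2 = compute_mfei(-34.6, seq + seq)
        assert mfei1 == pytest.approx(mfei2)

    def test_gc_free_sequence_is_an_error(self):
        with pytest.raises(ValueError):
            compute_mfei(-5.0, "AT" * 30)


class TestFilterMfei:
    def test_boundary_and_extremes(self):
        values = [{"mfei": 0.9699}, {"mfei": 0.97}, {"mfei": 2.4}]
        assert filter_mfei(values, 0.97) == values[1:]
        assert filter_mfei(values, 0.0) == values
        assert filter_mfei(values, math.inf) == []
        assert filter_mfei([], 0.97) == []


class TestCriteria:
    def test_all_pass_on_designed_hairpin(self):
        flags, arm, star = evaluate_criteria(_fold(), M0, M1, read_count=9)
        assert all(flags.values())
        assert arm == "5p"
        star_seq, star_start = star
        assert star_seq.startswith(revcomp(MATURE)[:20])

    def test_19nt_mature_fails_size_criterion(self):
        flags, _, _ = evaluate_criteria(_fold(), M0, M0 + 19, read_count=9)
        assert not flags["mature_on_stem"]

    def test_read_count_boundary_at_five(self):
        below, _, _ = evaluate_criteria(_fold(), M0, M1, read_count=4)
        at, _, _ = evaluate_criteria(_fold(), M0, M1, read_count=5)
        assert not below["read_count"] and at["read_count"]

    def test_mfe_boundary_at_minus_18(self):
        fail, _, _ = evaluate_criteria(_fold(mfe=-17.9), M0, M1, read_count=9)
        ok, _, _ = evaluate_criteria(_fold(mfe=-18.0), M0, M1, read_count=9)
        assert not fail["mfe"] and ok["mfe"]

    def test_mature_spanning_the_loop_fails_stem_criterion(self):
        flags, arm, star = evaluate_criteria(_fold(), 20, 42, read_count=9)
        assert arm == "unknown" and star is None
        assert not flags["mature_on_stem"]

    def test_unstructured_precursor_keeps_flags_but_fails_stem_criteria(self):
        fr = FoldResult("A" * 60, "." * 60, 0.0)
        flags, arm, star = evaluate_criteria(fr, 10, 32, read_count=9)
        assert star is None and arm == "unknown"
        assert flags["read_count"] and not flags["mature_on_stem"]
        assert not flags["size_and_spacing"] and not flags["asymmetry"]

    def test_large_bulge_fails_bulge_criterion(self):
        # force a 5-nt unpaired stretch inside the mature
        structure = list(fold_rna(PRECURSOR).structure)
        # make 5 mature positions unpaired together with their partners
        table_src = fold_rna(PRECURSOR)
        from mirskin.fold import pair_table

        table = pair_table(table_src.structure)
        for i in range(M0 + 8, M0 + 13):
            j = table[i]
            if j >= 0:
                structure[i] = "."
                structure[j] = "."
        fr = FoldResult(PRECURSOR, "".join(structure), table_src.mfe)
        flags, _, _ = evaluate_criteria(fr, M0, M1, read_count=9)
        assert not flags["bulge"]


class TestMergeLibraries:
    def test_published_set_sizes_merge_to_87(self):
        shared = [f"s{i}" for i in range(31)]
        lib_a = shared + [f"a{i}" for i in range(55 - 31)]
        lib_b = shared + [f"b{i}" for i in range(63 - 31)]
        merged = merge_libraries(lib_a, lib_b)
        assert len(merged.per_library["A"]) == 55
        assert len(merged.per_library["B"]) == 63
        assert len(merged.shared) == 31
        assert merged.union_count == 55 + 63 - 31 == 87

    def test_disjoint_sets_add(self):
        assert merge_libraries(["a", "b"], ["c", "d", "e"]).union_count == 5

    def test_subset_union_is_the_superset(self):
        assert merge_libraries(["a"], ["a", "b", "c"]).union_count == 3


@pytest.fixture(scope="module")
def predictions(sim_data, sim_tags, sim_annotator, sim_conserved_hits):
    records = sim_annotator.classify(sim_tags)
    exclude = {
        r.tag.sequence for r in records if r.category != UNANNOTATED
    } | {h.tag.sequence for h in sim_conserved_hits}
    return {
        lib: predict_novel(
            sim_tags, sim_data.genome, library_id=lib, exclude=exclude
        )
        for lib in ("white", "brown")
    }


class TestPlantedRecovery:
    def test_planted_precursors_recovered_with_high_precision(
        self, sim_data, predictions
    ):
        truth = {
            p.mature for p in sim_data.truth.planted_mirnas if p.kind == "novel"
        }
        merged = merge_libraries(
            passing(predictions["white"]), passing(predictions["brown"])
        )
        by_mature = {
            c.mature: c for lib in predictions for c in passing(predictions[lib])
        }
        final = {
            c.mature
            for c in filter_mfei([by_mature[m] for m in sorted(merged.union)], 0.97)
        }
        assert len(final & truth) / len(truth) >= 0.8
        assert len(final & truth) / len(final) >= 0.8

    def test_decoy_loci_do_not_pass(self, sim_data, predictions):
        decoy_seqs = set(sim_data._decoy_seqs.values())
        for cands in predictions.values():
            assert not any(c.mature in decoy_seqs for c in passing(cands))

    def test_candidate_evaluation_is_read_order_independent(self, sim_data, sim_tags):
        forward = predict_novel(sim_tags, sim_data.genome, library_id="white")
        backward = predict_novel(
            list(reversed(sim_tags)), sim_data.genome, library_id="white"
        )
        key = lambda c: (c.mature, c.locus, tuple(sorted(c.criteria.items())), c.mfei)
        assert sorted(map(key, forward)) == sorted(map(key, backward))
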