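"""NEL normalisation, fold changes, Audic-Claverie significance and the
comparative-CT qPCR path."""

import math
import random

import pandas as pd
import pytest

from mirskin.diffexpr import (
    analyze_qpcr,
    call_differential,
    count_significance,
    ddct_relative_quantity,
    fold_change,
    normalize_nel,
    qpcr_fold_changes,
    score_expression,
)
from mirskin.formats import CountTable
from mirskin.tables import expression_table


class TestNel:
    def test_zero_count_is_zero(self):
        assert normalize_nel(0, 10**6) == 0.0

    def test_per_million_definition(self):
        assert normalize_nel(10, 10**6) == 10.0

    def test_zero_total_is_an_error(self):
        with pytest.raises(ValueError):
            normalize_nel(1, 0)

    def test_nel_sums_to_one_million_over_a_library(self):
        rng = random.Random(5)
        counts = [rng.randint(0, 500) for _ in range(400)]
        total = sum(counts)
        assert sum(normalize_nel(c, total) for c in counts) == pytest.approx(1e6)


class TestFoldChange:
    def test_published_nel_pairs_give_published_fold_changes(self):
        """Spot rows of the white/brown skin expression table: the FC
        column is max(NEL)/min(NEL) with the direction naming the
        enriched coat colour."""
        table = expression_table().set_index("mirna_id")
        for mirna, printed_fc, direction in [
            ("miR-202", 47.7861, "white"),
            ("miR-211", 16.2860, "brown"),
        ]:
            row = table.loc[mirna]
            fc, d = fold_change(
                row["nel_brown"], row["nel_white"], labels=("brown", "white")
            )
            assert round(fc, 4) == printed_fc
            assert d == direction

    def test_equal_nel_gives_unit_fold_change(self):
        assert fold_change(3.3, 3.3)[0] == 1.0

    def test_symmetric_under_library_swap(self):
        fc_ab, d_ab = fold_change(2.0, 9.0, labels=("a", "b"))
        fc_ba, d_ba = fold_change(9.0, 2.0, labels=("b", "a"))
        assert fc_ab == fc_ba == 4.5
        assert d_ab == d_ba == "b"

    def test_both_zero_is_undefined(self):
        with pytest.raises(ValueError):
            fold_change(0.0, 0.0)


def ac_posterior_tail_bruteforce(x, n1, y, n2):
    """Direct summation of the count-comparison posterior: p(k | x) =
    C(x+k, k) q^k (1-q)^(x+1) with q = n2/(n1+n2); two-sided by doubling
    the smaller tail."""
    q = n2 / (n1 + n2)
    def pmf(k):
        return math.comb(x + k, k) * (q ** k) * ((1 - q) ** (x + 1))
    lower = sum(pmf(k) for k in range(0, y + 1))
    upper = 1.0 - sum(pmf(k) for k in range(0, y))
    return min(1.0, 2 * min(lower, upper))


class TestCountSignificance:
    def test_identical_counts_and_totals_are_not_significant(self):
        assert count_significance(25, 1000, 25, 1000) == pytest.approx(1.0)

    def test_p_decreases_as_the_contrast_grows(self):
        ps = [count_significance(0, 10**5, n, 10**5) for n in (5, 20, 80, 320)]
        assert all(a > b for a, b in zip(ps, ps[1:]))
        assert ps[-1] < 1e-10

    def test_matches_direct_summation_for_small_counts(self):
        for x in range(0, 51, 10):
            for y in range(0, 51, 7):
                fast = count_significance(x, 2000, y, 3000)
                slow = ac_posterior_tail_bruteforce(x, 2000, y, 3000)
                assert fast == pytest.approx(slow, abs=1e-6)

    def test_ztest_alternative_agrees_in_direction(self):
        p_ac = count_significance(10, 10**5, 200, 10**5)
        p_z = count_significance(10, 10**5, 200, 10**5, method="ztest")
        assert p_ac < 0.01 and p_z < 0.01


class TestCallDifferential:
    def _records(self):
        table = CountTable(
            ["b", "w"],
            {
                "strong": {"b": 20, "w": 400},   # FC >= 2, tiny p
                "weak_fc": {"b": 300, "w": 540}, # significant but FC 1.8
                "weak_p": {"b": 1, "w": 3},      # FC 3 but p large
                "null": {"b": 200, "w": 201},
            },
        )
        return score_expression(table, {"b": 10**5, "w": 10**5}, "b", "w")

    def test_fc_and_alpha_gates_both_required(self):
        called = call_differential(self._records(), min_fc=2.0, alpha=0.01)
        assert [r.mirna_id for r in called] == ["strong"]

    def test_output_invariant_to_record_order(self):
        recs = self._records()
        assert call_differential(recs) == call_differential(recs[::-1])

    def test_zero_in_both_libraries_skipped(self):
        table = CountTable(["b", "w"], {"gone": {"b": 0, "w": 0}, "ok": {"b": 5, "w": 5}})
        recs = score_expression(table, {"b": 1000, "w": 1000}, "b", "w")
        assert [r.mirna_id for r in recs] == ["ok"]

    def test_zero_in_one_library_gets_finite_reported_fc(self):
        table = CountTable(["b", "w"], {"m": {"b": 0, "w": 50}, "n": {"b": 10, "w": 10}})
        recs = score_expression(table, {"b": 1000, "w": 1000}, "b", "w")
        m = next(r for r in recs if r.mirna_id == "m")
        assert math.isfinite(m.fold_change) and m.direction == "w"


class TestComparativeCt:
    @pytest.mark.parametrize("ddct,rq", [(0.0, 1.0), (1.0, 0.5), (-3.0, 8.0)])
    def test_closed_form(self, ddct, rq):
        assert ddct_relative_quantity(20 + ddct, 15, 20, 15) == pytest.approx(rq)

    def test_nonfinite_ct_rejected(self):
        with pytest.raises(ValueError):
            ddct_relative_quantity(math.nan, 15, 20, 15)

    def _table(self, fc=4.0, noise=0.0, seed=0):
        rng = random.Random(seed)
        rows = []
        for cond, level in (("brown", 1.0), ("white", fc)):
            for rep in range(4):
                s = f"{cond}_{rep}"
                rows.append({"sample": s, "condition": cond, "assay": "U6",
                             "ct": 20 + rng.gauss(0, noise)})
                rows.append({"sample": s, "condition": cond, "assay": "miR-x",
                             "ct": 28 - math.log2(level) + rng.gauss(0, noise)})
        return pd.DataFrame(rows)

    def test_noise_free_table_recovers_planted_fold_exactly(self):
        rq = analyze_qpcr(self._table(fc=4.0), "U6", calibrator_condition="brown")
        fcs = qpcr_fold_changes(rq)
        assert fcs.loc[0, "fold_change"] == pytest.approx(4.0)
        assert fcs.loc[0, "direction"] == "white"
        # calibrator condition self-normalises to RQ 1
        cal = rq[rq["condition"] == "brown"]["rq"]
        assert cal.mean() == pytest.approx(1.0)

    def test_noisy_replicates_recover_fold_within_30pct_most_of_the_time(self):
        """With CT noise sd 0.2 on both reference and target assays and
        n=4 replicates, log2FC error is N(0, 0.2) (per-sample dCT var
        2*0.04, /4 per condition mean, *2 for the difference), so a
        +-30% band holds with probability Phi(1.90)-Phi(-2.58) ~ 0.966
        per seed; over 100 fixed seeds assert the 3-sigma lower bound."""
        ok = 0
        for seed in range(100):
            rq = analyze_qpcr(
                self._table(fc=4.0, noise=0.2, seed=seed), "U6", "brown"
            )
            est = qpcr_fold_changes(rq).loc[0, "fold_change"]
            ok += abs(est - 4.0) / 4.0 <= 0.30
        assert ok >= 91  # E[ok] ~ 96.6, sd ~ 1.8

    def test_missing_reference_assay_is_an_error(self):
        with pytest.raises(ValueError):
            analyze_qpcr(self._table().query("assay != 'U6'"), "U6")
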