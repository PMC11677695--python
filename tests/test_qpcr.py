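import math

import numpy as np
import pytest

from semark import (
    anova_tukey,
    fit_standard_curve,
    impute_undetected,
    relative_expression,
    relative_expression_table,
)
from semark.io import CtDataset, CtRecord
from semark.qpcr import StandardCurve, _compact_letter_display


def _panel(rows):
    """rows: (tissue, gene, rep, ct)"""
    return CtDataset(tuple(CtRecord(*r) for r in rows))


def _triplicate(tissue_values, target="TG", refs=("RPL2", "TBP1")):
    """tissue -> (target_ct, ref1_ct, ref2_ct), replicated 3x exactly."""
    rows = []
    for tissue, (tgt, r1, r2) in tissue_values.items():
        for rep in (1, 2, 3):
            rows += [
                (tissue, target, rep, tgt),
                (tissue, refs[0], rep, r1),
                (tissue, refs[1], rep, r2),
            ]
    return _panel(rows)


class TestStandardCurve:
    def test_perfect_tenfold_series_has_100pct_efficiency(self):
        points = [(10.0**k, 10 + 3.3219 * (9 - k)) for k in range(2, 10)]
        curve = fit_standard_curve(points, "CeNA1")
        assert curve.slope == pytest.approx(-3.3219, abs=1e-6)
        assert curve.r_squared == pytest.approx(1.0, abs=1e-12)
        assert curve.efficiency_pct == pytest.approx(100.0, abs=0.01)
        assert curve.qc_pass

    @pytest.mark.parametrize(
        "slope, efficiency",
        [(-3.6, 100 * (10 ** (1 / 3.6) - 1)), (-3.1, 100 * (10 ** (1 / 3.1) - 1))],
    )
    def test_suboptimal_slopes_fail_the_90_110_band(self, slope, efficiency):
        points = [(10.0**k, 40 + slope * k) for k in range(2, 10)]
        curve = fit_standard_curve(points, "g")
        assert curve.efficiency_pct == pytest.approx(efficiency, abs=1e-9)
        assert not curve.qc_pass

    def test_efficiency_identity_holds_bit_exactly(self):
        curve = StandardCurve("g", slope=-3.45, intercept=38.0, r_squared=0.999)
        assert curve.efficiency_pct == 100.0 * (10.0 ** (-1.0 / -3.45) - 1.0)

    def test_positive_slope_flagged_invalid_not_raised(self):
        points = [(10.0**k, 10 + 2.0 * k) for k in range(2, 6)]
        curve = fit_standard_curve(points, "g")
        assert curve.slope > 0 and not curve.qc_pass

    def test_fewer_than_three_levels_rejected(self):
        with pytest.raises(ValueError, match="3 distinct"):
            fit_standard_curve([(1e9, 10), (1e8, 13), (1e8, 13.1)], "g")


class TestImputeUndetected:
    def test_intercept_substituted_and_audited(self):
        ds = _panel([("nr", "CeNA1", 1, None), ("ec", "CeNA1", 1, 17.2)])
        curve = StandardCurve("CeNA1", slope=-3.3, intercept=41.2, r_squared=0.99)
        out, audit = impute_undetected(ds, {"CeNA1": curve})
        assert out.subset(gene="CeNA1", tissue="nr")[0].ct == 41.2
        assert out.subset(gene="CeNA1", tissue="ec")[0].ct == 17.2
        assert len(audit) == 1 and audit[0].imputed_ct == 41.2

    def test_no_undetected_records_is_identity(self):
        ds = _panel([("ec", "g", 1, 20.0)])
        out, audit = impute_undetected(ds, {})
        assert out == ds and audit == []

    def test_missing_curve_is_an_error_naming_the_gene(self):
        ds = _panel([("nr", "CeNA1", 1, None)])
        with pytest.raises(ValueError, match="CeNA1"):
            impute_undetected(ds, {})


class TestRelativeExpression:
    def test_calibrator_is_zero_by_construction(self):
        ds = _triplicate({"rl": (24, 20, 22), "ec": (23, 20, 22)})
        res = relative_expression(ds, "TG")
        assert res["rl"].log2_fc == 0.0

    def test_one_cycle_lower_doubles_expression(self):
        ds = _triplicate({"rl": (24, 20, 22), "ec": (23, 20, 22)})
        assert relative_expression(ds, "TG")["ec"].log2_fc == pytest.approx(1.0)

    def test_hand_worked_ddct_example_gives_rq_1024(self):
        # rl: dCt = 24 - mean(20,22) = 3; ec: dCt = 14 - mean(19,23) = -7
        # ddCt = -10, log2 fold change 10, RQ 1024
        ds = _triplicate({"rl": (24, 20, 22), "ec": (14, 19, 23)})
        entry = relative_expression(ds, "TG")["ec"]
        assert entry.log2_fc == pytest.approx(10.0)
        assert 2.0**entry.log2_fc == pytest.approx(1024.0)

    def test_shift_invariance_of_delta_ct(self):
        # adding c to target AND references of one tissue leaves dCt unchanged
        base = {"rl": (24, 20, 22), "ec": (18, 19, 21)}
        shifted = {"rl": (24, 20, 22), "ec": (18 + 2.5, 19 + 2.5, 21 + 2.5)}
        a = relative_expression(_triplicate(base), "TG")["ec"].log2_fc
        b = relative_expression(_triplicate(shifted), "TG")["ec"].log2_fc
        assert a == pytest.approx(b)

    def test_se_over_replicates(self):
        rows = []
        for rep, tgt in enumerate([23.0, 24.0, 25.0], start=1):
            rows += [("rl", "TG", rep, 24.0), ("rl", "RPL2", rep, 20.0), ("rl", "TBP1", rep, 22.0),
                     ("ec", "TG", rep, tgt), ("ec", "RPL2", rep, 20.0), ("ec", "TBP1", rep, 22.0)]
        entry = relative_expression(_panel(rows), "TG")["ec"]
        assert entry.n == 3
        assert entry.se == pytest.approx(1.0 / math.sqrt(3))

    def test_missing_reference_measurement_is_an_error(self):
        rows = [("rl", "TG", 1, 24.0), ("rl", "RPL2", 1, 20.0)]
        with pytest.raises(ValueError, match="TBP1"):
            relative_expression(_panel(rows), "TG")

    def test_absent_calibrator_is_an_error(self):
        ds = _triplicate({"ec": (14, 19, 23)})
        with pytest.raises(ValueError, match="rl"):
            relative_expression(ds, "TG", calibrator="rl")

    def test_undetected_ct_requires_prior_imputation(self):
        rows = [("rl", "TG", 1, None), ("rl", "RPL2", 1, 20.0), ("rl", "TBP1", 1, 22.0)]
        with pytest.raises(ValueError, match="impute"):
            relative_expression(_panel(rows), "TG")


class TestAnovaTukey:
    def test_identically_distributed_groups_share_one_letter(self):
        rng = np.random.default_rng(1)
        values = {t: list(rng.normal(0, 1, 5)) for t in ("rl", "ec", "gse")}
        res = anova_tukey(values, alpha=0.05)
        assert set(res.letters.values()) == {"a"}

    def test_three_separated_groups_get_three_letters(self):
        values = {
            "lo": [-0.1, 0.0, 0.1],
            "mid": [4.9, 5.0, 5.1],
            "hi": [9.9, 10.0, 10.1],
        }
        res = anova_tukey(values, alpha=0.05)
        assert sorted(res.letters.values()) == ["a", "b", "c"]
        assert res.letters["hi"] == "a"  # letters follow descending means

    def test_two_clearly_separated_groups(self):
        res = anova_tukey({"a": [0.0, 0.1, -0.1], "b": [5.0, 5.1, 4.9]}, alpha=0.05)
        assert res.letters["b"] == "a" and res.letters["a"] == "b"

    def test_letters_consistent_with_pairwise_significance(self):
        rng = np.random.default_rng(7)
        values = {f"t{i}": list(rng.normal(i * 0.8, 1.0, 4)) for i in range(5)}
        res = anova_tukey(values, alpha=0.05)
        for g1 in values:
            for g2 in values:
                if g1 >= g2:
                    continue
                share = bool(set(res.letters[g1]) & set(res.letters[g2]))
                significant = frozenset((g1, g2)) in res.significant_pairs
                assert share != significant

    def test_degenerate_zero_variance_everywhere_rejected(self):
        with pytest.raises(ValueError, match="zero within-group variance"):
            anova_tukey({"a": [1.0, 1.0], "b": [2.0, 2.0]})

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="two tissues"):
            anova_tukey({"a": [1.0, 2.0]})


class TestCompactLetterDisplay:
    def test_chain_pattern_yields_overlapping_letters(self):
        # a != c significant; b overlaps both
        letters = _compact_letter_display(
            ["a", "b", "c"],
            {"a": 3.0, "b": 2.0, "c": 1.0},
            {frozenset(("a", "c"))},
        )
        assert set(letters["b"]) == set(letters["a"]) | set(letters["c"])
        assert not set(letters["a"]) & set(letters["c"])


class TestRelativeExpressionTable:
    def test_letters_and_calibrator_flag(self):
        rng = np.random.default_rng(3)
        rows = []
        for tissue, shift in [("rl", 0.0), ("ec", -8.0), ("gse", 0.0)]:
            for rep in (1, 2, 3):
                rows += [
                    (tissue, "TG", rep, 24.0 + shift + rng.normal(0, 0.05)),
                    (tissue, "RPL2", rep, 20.0 + rng.normal(0, 0.05)),
                    (tissue, "TBP1", rep, 22.0 + rng.normal(0, 0.05)),
                ]
        table = relative_expression_table(_panel(rows), ["TG"])
        assert table.entries[("TG", "ec")].log2_fc == pytest.approx(8.0, abs=0.3)
        assert table.entries[("TG", "ec")].sig_vs_calibrator
        assert not table.entries[("TG", "gse")].sig_vs_calibrator
        assert table.entries[("TG", "rl")].letters != table.entries[("TG", "ec")].letters
        frame = table.to_frame()
        assert set(frame.columns) >= {"gene", "tissue", "log2_fc", "se", "letters"}
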