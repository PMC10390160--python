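"""Group statistics: normality screen, t-tests, ANOVA, comparison report."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mousehrv import (
    GroupComparison,
    anova_oneway,
    compare_groups,
    shapiro_wilk,
    significance_grade,
    t_test_independent,
    welch_t_from_summary,
)


class TestShapiroWilk:
    def test_too_small_sample_rejected(self):
        with pytest.raises(ValueError):
            shapiro_wilk([1.0, 2.0])

    def test_type_one_error_control_on_gaussian(self):
        hits = 0
        for seed in range(100):
            x = np.random.default_rng(seed).standard_normal(7)
            if shapiro_wilk(x).p_value > 0.05:
                hits += 1
        assert hits >= 90

    def test_two_point_mixture_scores_lower_w(self):
        lower = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            g = rng.standard_normal(7)
            mix = np.where(rng.random(7) < 0.5, -5.0, 5.0) + 0.01 * rng.standard_normal(7)
            if shapiro_wilk(mix).statistic < shapiro_wilk(g).statistic:
                lower += 1
        assert lower >= 15


class TestTTests:
    def test_identical_groups_null(self):
        res = t_test_independent([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_pooled_hand_computation(self):
        res = t_test_independent([1, 2, 3], [4, 5, 6], equal_var=True)
        assert res.statistic == pytest.approx(-3.674, abs=1e-3)
        assert res.p_value == pytest.approx(0.0214, abs=2e-3)

    def test_swap_symmetry(self):
        a, b = [1.0, 2.0, 4.0], [3.0, 6.0, 7.0]
        r1 = t_test_independent(a, b)
        r2 = t_test_independent(b, a)
        assert r1.statistic == pytest.approx(-r2.statistic, rel=1e-12)
        assert r1.p_value == pytest.approx(r2.p_value, rel=1e-12)

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            t_test_independent([1.0], [2.0, 3.0])
        with pytest.raises(ValueError):
            t_test_independent([2.0, 2.0], [2.0, 2.0])


class TestWelchFromSummary:
    def test_group_hr_summaries_strongly_separate(self):
        res = welch_t_from_summary(253.81, 34.61, 7, 376.39, 23.62, 7)
        assert abs(res.statistic) == pytest.approx(7.74, abs=0.02)
        assert res.p_value < 0.01

    def test_group_sdnn_summaries(self):
        res = welch_t_from_summary(8.57, 3.69, 7, 2.498, 1.00, 7)
        assert abs(res.statistic) == pytest.approx(4.2, abs=0.05)

    def test_equal_means_null(self):
        res = welch_t_from_summary(5.0, 1.0, 7, 5.0, 2.0, 7)
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_matches_raw_data_welch_exactly(self, rng):
        a = rng.normal(10, 2, size=9)
        b = rng.normal(12, 3, size=7)
        raw = t_test_independent(a, b, equal_var=False)
        summ = welch_t_from_summary(a.mean(), a.std(ddof=1), a.size,
                                    b.mean(), b.std(ddof=1), b.size)
        assert summ.statistic == pytest.approx(raw.statistic, abs=1e-10)
        assert summ.df == pytest.approx(raw.df, abs=1e-10)
        assert summ.p_value == pytest.approx(raw.p_value, abs=1e-10)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            welch_t_from_summary(1.0, 1.0, 1, 2.0, 1.0, 7)
        with pytest.raises(ValueError):
            welch_t_from_summary(1.0, -1.0, 7, 2.0, 1.0, 7)


class TestAnova:
    def test_identical_groups_f_zero(self):
        g = [1.0, 2.0, 3.0]
        res = anova_oneway(g, g, g)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_computed_f(self):
        res = anova_oneway([1, 2, 3], [2, 3, 4], [3, 4, 5])
        assert res.statistic == pytest.approx(3.0, abs=1e-12)
        assert res.df == 2

    def test_two_groups_rejected(self):
        with pytest.raises(ValueError):
            anova_oneway([1, 2, 3], [4, 5, 6])

    def test_forced_two_group_f_equals_t_squared(self, rng):
        a = rng.normal(0, 1, 8)
        b = rng.normal(1, 1, 8)
        from scipy.stats import f_oneway

        f = f_oneway(a, b).statistic
        t = t_test_independent(a, b, equal_var=True).statistic
        assert f == pytest.approx(t**2, rel=1e-10)

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(c=st.floats(0.1, 10.0), d=st.floats(-5.0, 5.0))
    def test_p_invariant_to_affine_rescaling(self, c, d):
        rng = np.random.default_rng(2)
        gs = [rng.normal(i, 1, 6) for i in range(3)]
        p0 = anova_oneway(*gs).p_value
        p1 = anova_oneway(*[c * g + d for g in gs]).p_value
        assert p1 == pytest.approx(p0, rel=1e-9)


def _tidy(groups: dict[str, dict[str, list[float]]]) -> pd.DataFrame:
    rows = []
    for g, metrics in groups.items():
        for metric, vals in metrics.items():
            for i, v in enumerate(vals):
                rows.append({"subject": f"{g}{i}", "group": g,
                             "metric": metric, "value": v})
    return pd.DataFrame(rows)


class TestCompareGroups:
    def test_full_report_structure(self):
        table = _tidy({
            "KX": {"hr": [250, 260, 255, 248, 252, 251, 258]},
            "P": {"hr": [370, 380, 375, 372, 371, 379, 377]},
            "PF": {"hr": [372, 383, 376, 370, 378, 381, 374]},
        })
        report = compare_groups(table)
        entry = report["metrics"]["hr"]
        assert set(entry["summaries"]) == {"KX", "P", "PF"}
        assert entry["anova"]["p"] < 0.001
        assert entry["pairwise"]["KX_vs_P"]["p"] < 0.01
        assert entry["pairwise"]["KX_vs_P"]["grade"] in ("**", "***")
        assert entry["pairwise"]["P_vs_PF"]["p"] > 0.05

    def test_single_group_summaries_with_warning(self):
        table = _tidy({"KX": {"hr": [250.0, 260.0, 255.0]}})
        with pytest.warns(UserWarning, match="single-group"):
            report = compare_groups(table)
        assert report["metrics"]["hr"]["summaries"]["KX"]["n"] == 3
        assert report["metrics"]["hr"]["anova"] is None

    def test_undersized_group_rejected(self):
        table = _tidy({"KX": {"hr": [250.0, 251.0]}, "P": {"hr": [370.0]}})
        with pytest.raises(ValueError, match="fewer than 2"):
            compare_groups(table)

    def test_unknown_metric_passes_through_with_warning(self):
        table = _tidy({"KX": {"weird": [1.0, 2.0, 3.0]},
                       "P": {"weird": [2.0, 3.0, 4.0]}})
        with pytest.warns(UserWarning, match="unrecognized"):
            report = compare_groups(table, known_metrics=("hr",))
        assert "weird" in report["metrics"]

    def test_holm_correction_monotone(self):
        table = _tidy({
            "KX": {"hr": [250, 260, 255, 248, 252, 251, 258]},
            "P": {"hr": [370, 380, 375, 372, 371, 379, 377]},
            "PF": {"hr": [375, 385, 380, 377, 376, 384, 382]},
        })
        report = compare_groups(table, holm=True)
        for res in report["metrics"]["hr"]["pairwise"].values():
            assert res["p_holm"] >= res["p"]

    def test_model_results_summary(self):
        table = _tidy({
            "KX": {"sdnn": [8.0, 9.0, 8.5, 7.9, 9.2]},
            "PF": {"sdnn": [2.4, 2.6, 2.5, 2.3, 2.7]},
        })
        res = GroupComparison.from_dataframe(table).fit()
        text = res.summary()
        assert "sdnn" in text and "KX_vs_PF" in text
        frame = res.pairwise_frame()
        assert {"metric", "pair", "t", "p"}.issubset(frame.columns)


def test_significance_grades():
    assert significance_grade(0.2) == "ns"
    assert significance_grade(0.03) == "*"
    assert significance_grade(0.005) == "**"
    assert significance_grade(0.0005) == "***"
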