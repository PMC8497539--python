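"""Trial statistics: baseline subtraction, outlier screening, t and
Mann-Whitney tests (with independent oracles), full report structure."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from swallowtrack.synth import generate_trial
from swallowtrack.trial import (
    ARMS,
    TrialAnalysisConfig,
    TrialTable,
    SubjectRecord,
    baseline_subtract,
    exclude_outliers,
    grubbs_screen,
    holm_adjust,
    mann_whitney_u,
    run_trial_analysis,
    subject_changes,
    ttest_from_summary,
    ttest_independent,
)


def make_table(pre_plus, pre_minus, follow=None):
    """Minimal trial table from two lists of baseline distances."""
    rows = []
    for arm, values in (("AA+", pre_plus), ("AA-", pre_minus)):
        for i, v in enumerate(values):
            f = follow[arm][i] if follow else v
            rows.append({"id": f"{arm}{i}", "arm": arm, "sex": "F",
                         "age_years": 40, "height_cm": 160.0,
                         "distance_pre": v, "distance_2wk": f,
                         "distance_3mo": f, "distance_9mo": f})
    return TrialTable(pd.DataFrame(rows))


class TestBaselineSubtract:
    def test_control_arm_2wk_change(self):
        # 6.14 mm at 2 weeks minus 4.1 mm preoperative = 2.04 mm
        rec = SubjectRecord("s", "AA-", "F", 40, 160,
                            {"pre": 4.1, "2wk": 6.14})
        assert subject_changes(rec)["2wk"] == pytest.approx(2.04)

    def test_no_change_and_negative_change(self):
        rec = SubjectRecord("s", "AA+", "F", 40, 160,
                            {"pre": 5.0, "2wk": 5.0, "3mo": 4.0})
        ch = subject_changes(rec)
        assert ch["2wk"] == 0.0
        assert ch["3mo"] == -1.0

    def test_missing_baseline_flagged(self):
        rec = SubjectRecord("s", "AA+", "F", 40, 160, {"2wk": 5.0})
        with pytest.raises(ValueError, match="baseline"):
            subject_changes(rec)

    def test_table_version_propagates_nan_for_missing_baseline(self):
        table = make_table([4.0, 5.0, 6.0], [4.0, 5.0, 6.0])
        table.data.loc[0, "distance_pre"] = np.nan
        ch = baseline_subtract(table)
        assert ch["change_2wk"].isna()[0]
        assert ch["change_2wk"].notna()[1:].all()


class TestOutlierExclusion:
    def test_injected_6sd_outlier_removed_by_grubbs(self, rng):
        base = rng.normal(4.0, 1.0, 49)
        spike = base.copy()
        spike[7] = base.mean() + 6 * base.std(ddof=1)
        table = make_table(list(spike), list(rng.normal(4.0, 1.0, 49)))
        out = exclude_outliers(table, "distance_pre", alpha=0.05)
        assert "AA+7" in set(out.exclusions["id"])
        assert "AA+7" not in set(out.data["id"])

    def test_all_equal_arm_has_no_exclusions(self):
        table = make_table([4.0] * 10, [4.0] * 10)
        out = exclude_outliers(table, "distance_pre")
        assert len(out.exclusions) == 0
        assert len(out) == 20

    def test_fixed_count_mode_49_to_44_per_arm(self, rng):
        table = make_table(list(rng.normal(4, 1, 49)),
                           list(rng.normal(4, 1, 49)))
        out = exclude_outliers(table, "distance_pre", mode="fixed_count", k=5)
        for arm in ARMS:
            assert (out.data["arm"] == arm).sum() == 44
            assert (out.exclusions["arm"] == arm).sum() == 5

    def test_invalid_alpha_rejected(self):
        table = make_table([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            exclude_outliers(table, "distance_pre", alpha=1.5)

    def test_grubbs_screen_keeps_clean_normal_sample(self, rng):
        keep, removals = grubbs_screen(rng.normal(0, 1, 30), alpha=0.01)
        assert removals == [] or len(removals) <= 1  # rare false positive

    def test_excluded_and_analyzed_ids_disjoint(self, rng):
        table = make_table(list(rng.normal(4, 1, 20)),
                           list(rng.normal(4, 1, 20)))
        out = exclude_outliers(table, "distance_pre", mode="fixed_count", k=3)
        assert not set(out.data["id"]) & set(out.exclusions["id"])


def _t_tail_probability(t_abs: float, df: int, n_grid: int = 400_000) -> float:
    """Two-sided t tail by numerical integration of the density (oracle)."""
    hi = max(10 * t_abs, 60.0)
    x = np.linspace(t_abs, hi, n_grid)
    log_norm = (math.lgamma((df + 1) / 2) - math.lgamma(df / 2)
                - 0.5 * math.log(df * math.pi))
    pdf = np.exp(log_norm - (df + 1) / 2 * np.log1p(x ** 2 / df))
    return 2 * float(np.trapezoid(pdf, x))


class TestTTest:
    def test_pooled_matches_closed_form_oracle(self):
        x, y = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        res = ttest_independent(x, y, variant="pooled")
        # closed form: sp^2 = 1, t = -3 / sqrt(2/3), df = 4
        t_expected = -3.0 / math.sqrt(2.0 / 3.0)
        assert res.statistic == pytest.approx(t_expected, rel=1e-12)
        assert res.statistic == pytest.approx(-3.674, abs=5e-4)
        p_expected = _t_tail_probability(abs(t_expected), 4)
        assert res.p_value == pytest.approx(p_expected, abs=1e-5)
        assert res.p_value == pytest.approx(0.021312, abs=1e-5)

    def test_identical_samples_give_p_one(self):
        res = ttest_independent([2.0, 2.0, 2.0], [2.0, 2.0, 2.0])
        assert res.p_value == 1.0

    def test_requires_two_values_per_sample(self):
        with pytest.raises(ValueError):
            ttest_independent([1.0], [2.0, 3.0])

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            ttest_independent([1, 2], [3, 4], variant="z")

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.lists(st.floats(-50, 50), min_size=3, max_size=8),
           st.lists(st.floats(-50, 50), min_size=3, max_size=8))
    def test_summary_input_equals_raw_input_pooled(self, x, y):
        x, y = np.array(x), np.array(y)
        if x.std(ddof=1) == 0 and y.std(ddof=1) == 0:
            return
        raw = ttest_independent(x, y, variant="pooled")
        summ = ttest_from_summary(x.mean(), x.std(ddof=1), len(x),
                                  y.mean(), y.std(ddof=1), len(y),
                                  variant="pooled")
        assert summ.statistic == pytest.approx(raw.statistic, abs=1e-12, rel=1e-12)
        assert summ.p_value == pytest.approx(raw.p_value, abs=1e-12, rel=1e-12)

    def test_reported_9mo_summaries_significant(self):
        res = ttest_from_summary(1.45, 1.66, 44, 0.58, 1.5, 44)
        assert res.p_value < 0.05
        assert res.p_value == pytest.approx(0.013, abs=0.002)


def _mwu_exact_enumeration(x, y):
    """Independent oracle: U of x and exact two-sided p by enumerating all
    C(n+m, n) placements of the x-ranks (distinct values only)."""
    n, m = len(x), len(y)
    combined = sorted(x + y)
    ranks = {v: i + 1 for i, v in enumerate(combined)}
    u_obs = sum(ranks[v] for v in x) - n * (n + 1) / 2
    mu = n * m / 2
    us = []
    for ranks_x in itertools.combinations(range(1, n + m + 1), n):
        us.append(sum(ranks_x) - n * (n + 1) / 2)
    us = np.array(us)
    p = np.mean(np.abs(us - mu) >= abs(u_obs - mu) - 1e-12)
    return u_obs, min(1.0, float(p))


class TestMannWhitney:
    def test_disjoint_samples_exact_p(self):
        res = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(0.1)

    def test_single_observations(self):
        res = mann_whitney_u([1.0], [2.0])
        assert res.p_value == pytest.approx(1.0)

    def test_identical_multisets_give_half_n_squared(self):
        x = [1.0, 2.0, 3.0]
        res = mann_whitney_u(x, x)
        assert res.statistic == pytest.approx(len(x) ** 2 / 2)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])

    def test_exact_branch_matches_enumeration_for_small_samples(self, rng):
        for n, m in [(1, 2), (2, 2), (3, 2), (3, 3), (4, 3), (4, 4), (5, 3)]:
            vals = rng.permutation(np.arange(1.0, n + m + 1))
            x, y = list(vals[:n]), list(vals[n:])
            res = mann_whitney_u(x, y)
            u_oracle, p_oracle = _mwu_exact_enumeration(x, y)
            assert res.statistic == pytest.approx(u_oracle)
            assert res.p_value == pytest.approx(p_oracle, abs=1e-12)
            assert "exact" in res.test

    def test_ties_fall_back_to_corrected_normal_approximation(self):
        res = mann_whitney_u([1, 1, 2, 3], [2, 2, 3, 4])
        assert "asymptotic" in res.test
        assert 0 <= res.p_value <= 1


class TestHolm:
    def test_monotone_and_bounded(self):
        adj = holm_adjust([0.01, 0.04, 0.03])
        assert adj[0] == pytest.approx(0.03)
        assert all(0 <= a <= 1 for a in adj)
        assert adj[1] >= 0.04 and adj[2] >= 0.03


class TestRunTrialAnalysis:
    def test_single_arm_rejected(self):
        rows = [{"id": f"s{i}", "arm": "AA+", "sex": "F", "age_years": 30,
                 "height_cm": 150.0, "distance_pre": 4.0, "distance_2wk": 5.0,
                 "distance_3mo": 5.0, "distance_9mo": 5.0} for i in range(5)]
        with pytest.raises(ValueError, match="both arms"):
            run_trial_analysis(TrialTable(pd.DataFrame(rows)))

    def test_report_structure_and_subject_bookkeeping(self):
        table = generate_trial(n_per_arm=20, seed=5)
        report = run_trial_analysis(table)
        assert set(report["actual"]) == {f"distance_{t}" for t in
                                         ("pre", "2wk", "3mo", "9mo")}
        assert set(report["change"]) == {f"change_{t}" for t in
                                         ("2wk", "3mo", "9mo")}
        entry = report["change"]["change_2wk"]
        assert entry["testable"]
        assert len(entry["subject_ids"]["AA+"]) == entry["n1"] == 20
        assert 0 <= entry["p_value"] <= 1

    def test_strata_partition_subjects_exactly(self):
        table = generate_trial(n_per_arm=30, seed=9)
        cfg = TrialAnalysisConfig(age_split_years=50, height_split_cm=160)
        report = run_trial_analysis(table, cfg)
        df = table.data
        young = report["subgroups"]["age:20-49"]["n"]
        old = report["subgroups"]["age:50+"]["n"]
        for arm in ARMS:
            sub = df[df["arm"] == arm]
            assert young[arm] == (sub["age_years"] < 50).sum()
            assert old[arm] == (sub["age_years"] >= 50).sum()
            assert young[arm] + old[arm] == 30
        short = report["subgroups"]["height:<160cm"]["n"]
        tall = report["subgroups"]["height:>=160cm"]["n"]
        for arm in ARMS:
            assert short[arm] + tall[arm] == 30

    def test_empty_stratum_reported_not_testable(self):
        table = generate_trial(n_per_arm=10, seed=2)
        table.data["sex"] = "F"  # no men at all
        report = run_trial_analysis(table)
        male = report["subgroups"]["sex:male"]
        assert male["n"] == {"AA+": 0, "AA-": 0}
        assert not male["change_2wk"]["testable"]

    def test_fixed_count_outliers_reflected_in_n(self):
        table = generate_trial(n_per_arm=49, seed=3)
        cfg = TrialAnalysisConfig(outlier_mode="fixed_count", outlier_k=5,
                                  outlier_endpoint="change_2wk")
        report = run_trial_analysis(table, cfg)
        assert report["n_analyzed"] == {"AA+": 44, "AA-": 44}
        assert len(report["exclusions"]) == 10

    def test_mean_of_differences_equals_difference_of_means(self):
        # complete data: the change-endpoint arm mean equals the difference
        # of the actual-distance arm means
        table = generate_trial(n_per_arm=15, seed=8)
        report = run_trial_analysis(table)
        for tp in ("2wk", "3mo", "9mo"):
            act = report["actual"][f"distance_{tp}"]
            pre = report["actual"]["distance_pre"]
            ch = report["change"][f"change_{tp}"]
            assert ch["mean1"] == pytest.approx(act["mean1"] - pre["mean1"],
                                                abs=1e-9)
            assert ch["mean2"] == pytest.approx(act["mean2"] - pre["mean2"],
                                                abs=1e-9)
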