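"""Tests of the study-level statistical analyses."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from cvquant import (StudyConfig, cytokine_matrix, generate_study,
                     group_change_tests, leakage_regression, stage_contrasts)
from cvquant.stats import (group_mean_differences, holm_adjust,
                           independent_ttest, paired_ttest, records_to_frame)
from cvquant.synthetic import CytokineSpec


def make_frame(values_by_group, eyes_per_group=3, reps=1, noise=0.0, seed=0):
    """Small study table: values per stage group, optional eye-level noise."""
    rng = np.random.default_rng(seed)
    stage_of_group = {"1-2": 1, "3": 3, "4-5": 4}
    rows = []
    eye_id = 0
    for group, mean in values_by_group.items():
        for _ in range(eyes_per_group):
            eye_id += 1
            eye_offset = rng.normal(0, noise)
            for _ in range(reps):
                rows.append({"eye": f"e{eye_id}", "week": 0,
                             "arm": "re-suture",
                             "stage": stage_of_group[group],
                             "VD": mean + eye_offset + rng.normal(0, noise / 2 + 1e-12)})
    return pd.DataFrame(rows)


class TestStageContrasts:
    def test_equal_group_means_null(self):
        df = make_frame({"1-2": 20.0, "3": 20.0})
        df["VD"] += np.tile([-1.0, 0.0, 1.0], 2)  # same spread in each group
        res = stage_contrasts(df, "VD")
        assert res.mean_differences["3"] == pytest.approx(0.0, abs=1e-9)
        assert res.p_values["3"] > 0.99

    def test_single_record_per_eye_reduces_to_group_means(self):
        df = make_frame({"1-2": 40.0, "3": 13.0, "4-5": 27.0}, noise=0.0)
        df["VD"] += np.linspace(0, 1, len(df))  # deterministic jitter
        res = stage_contrasts(df, "VD")
        assert res.model == "ols"
        means = df.groupby(df["stage"].map({1: "1-2", 3: "3", 4: "4-5"}))["VD"].mean()
        assert res.mean_differences["3"] == pytest.approx(means["1-2"] - means["3"])
        assert res.mean_differences["4-5"] == pytest.approx(means["1-2"] - means["4-5"])

    def test_mixed_model_recovers_true_differences(self):
        diffs3, diffs45 = [], []
        for s in range(100):
            df = make_frame({"1-2": 40.0, "3": 13.0, "4-5": 27.0},
                            eyes_per_group=4, reps=3, noise=3.0, seed=s)
            res = stage_contrasts(df, "VD")
            diffs3.append(res.mean_differences["3"])
            diffs45.append(res.mean_differences["4-5"])
        # unbiased recovery: simulation mean within its 95% CI of truth
        for est, truth in ((diffs3, 27.0), (diffs45, 13.0)):
            mean = np.mean(est)
            half = 1.96 * np.std(est, ddof=1) / np.sqrt(len(est))
            assert abs(mean - truth) <= half + 0.25

    def test_missing_group_reported_missing(self):
        df = make_frame({"1-2": 30.0, "3": 15.0})
        res = stage_contrasts(df, "VD")
        assert res.mean_differences["4-5"] is None
        assert res.p_values["4-5"] is None

    def test_printed_summary_difference_convention(self):
        diffs = group_mean_differences({"1-2": 40.46, "3": 13.14, "4-5": 27.29})
        assert diffs["3"] == pytest.approx(27.32)
        assert diffs["4-5"] == pytest.approx(13.17)


class TestLeakageRegression:
    def test_perfect_negative_line(self):
        df = pd.DataFrame({"eye": list("abcde"), "week": 0, "arm": "x",
                           "VD": [10.0, 20, 30, 40, 50],
                           "leakage_s": [200.0, 160, 120, 80, 40]})
        res = leakage_regression(df)
        assert res.r == pytest.approx(-1.0)
        assert res.r_squared == pytest.approx(1.0)
        assert res.slope == pytest.approx(-4.0)

    def test_slope_recovery_on_generator_output(self):
        slopes = []
        for s in range(200):
            cfg = StudyConfig(arm_sizes={"re-suture": 10}, seed=50_000 + s)
            records, _ = generate_study(cfg)
            df = records_to_frame(records)
            df["VD"] = df["true_vd"]
            slopes.append(leakage_regression(df).slope)
        assert np.median(slopes) == pytest.approx(-4.0, rel=0.25)

    def test_too_few_records_rejected(self):
        df = pd.DataFrame({"eye": ["a", "b"], "week": 0, "arm": "x",
                           "VD": [10.0, 20.0], "leakage_s": [100.0, 50.0]})
        with pytest.raises(ValueError):
            leakage_regression(df)

    def test_degenerate_predictor_rejected(self):
        df = pd.DataFrame({"eye": list("abcd"), "week": 0, "arm": "x",
                           "VD": [10.0] * 4, "leakage_s": [1.0, 2, 3, 4]})
        with pytest.raises(ValueError, match="VD"):
            leakage_regression(df)


class TestCytokineMatrix:
    def test_perfect_monotone_and_antitone(self):
        df = pd.DataFrame({"eye": list("abcdef"), "week": 0, "arm": "x",
                           "VD": [1.0, 2, 3, 4, 5, 6],
                           "VBA": [6.0, 5, 4, 3, 2, 1],
                           "up": [10.0, 20, 30, 40, 50, 60]})
        cm = cytokine_matrix(df, analytes=["up"])
        assert cm.rho["up"]["VD"] == pytest.approx(1.0)
        assert cm.rho["up"]["VBA"] == pytest.approx(-1.0)

    def test_tied_data_matches_rank_then_pearson_oracle(self):
        vd = np.array([3.0, 1, 4, 1, 5, 9, 2, 6])
        an = np.array([2.0, 7, 1, 8, 2, 8, 1, 8])  # heavy ties
        df = pd.DataFrame({"eye": list("abcdefgh"), "week": 0, "arm": "x",
                           "VD": vd, "VBA": vd, "cyt": an})
        cm = cytokine_matrix(df, analytes=["cyt"])
        oracle = np.corrcoef(sps.rankdata(an), sps.rankdata(vd))[0, 1]
        assert cm.rho["cyt"]["VD"] == pytest.approx(oracle, abs=1e-12)

    def test_below_lod_analyte_excluded_and_logged(self):
        records, _ = generate_study(StudyConfig(seed=4))
        cm = cytokine_matrix(records, max_week=2)
        assert "VEGF-A" in cm.excluded_below_lod
        assert "VEGF-A" not in cm.rho

    def test_sparse_cells_flagged(self):
        df = pd.DataFrame({"eye": list("abcd"), "week": 0, "arm": "x",
                           "VD": [1.0, 2, 3, 4], "VBA": [1.0, 2, 3, 4],
                           "cyt": [5.0, np.nan, np.nan, np.nan]})
        cm = cytokine_matrix(df, analytes=["cyt"])
        assert cm.rho["cyt"]["VD"] is None
        assert cm.n["cyt"]["VD"] == 1


class TestGroupChangeTests:
    def _frame(self, pre_post_by_arm):
        rows = []
        for arm, eyes in pre_post_by_arm.items():
            for i, (pre, post) in enumerate(eyes):
                rows.append({"eye": f"{arm}{i}", "week": 2, "arm": arm, "VD": pre})
                rows.append({"eye": f"{arm}{i}", "week": 4, "arm": arm, "VD": post})
        return pd.DataFrame(rows)

    def test_identical_pre_post_exact_null(self):
        df = self._frame({"aflibercept": [(30.0, 30.0)] * 3,
                          "saline": [(25.0, 25.0)] * 2})
        res = group_change_tests(df)
        assert res["paired"]["aflibercept"] == pytest.approx(
            {"t": 0.0, "p": 1.0, "n": 3, "mean_change": 0.0})
        assert res["independent"]["p"] == pytest.approx(1.0)

    def test_orphaned_eyes_rejected_by_name(self):
        df = self._frame({"aflibercept": [(30.0, 20.0)] * 3,
                          "saline": [(25.0, 24.0)] * 2})
        df = df.drop(df[(df.eye == "aflibercept1") & (df.week == 4)].index)
        with pytest.raises(ValueError, match="aflibercept1"):
            group_change_tests(df)

    def test_paired_power_matches_noncentral_t(self):
        rng = np.random.default_rng(99)
        n, shift_sd, reps = 10, 1.0, 1000
        rejections = 0
        for _ in range(reps):
            pre = rng.standard_normal(n)
            delta = rng.standard_normal(n) + shift_sd
            _t, p = paired_ttest(pre, pre + delta)
            rejections += p < 0.05
        nc = shift_sd * np.sqrt(n)
        tcrit = sps.t.ppf(0.975, n - 1)
        power = (1 - sps.nct.cdf(tcrit, n - 1, nc)
                 + sps.nct.cdf(-tcrit, n - 1, nc))
        assert rejections / reps == pytest.approx(power, abs=0.05)

    def test_paired_type_one_error_calibrated(self):
        rng = np.random.default_rng(7)
        rejections = 0
        reps = 2000
        for _ in range(reps):
            _t, p = paired_ttest(rng.standard_normal(10), rng.standard_normal(10))
            rejections += p < 0.05
        assert rejections / reps == pytest.approx(0.05, abs=0.02)

    def test_independent_equal_constant_arms_null(self):
        t, p = independent_ttest([1.0, 1.0, 1.0], [1.0, 1.0])
        assert (t, p) == (0.0, 1.0)


def test_holm_adjustment_monotone_and_bounded():
    raw = [0.01, 0.04, 0.03, 0.5]
    adj = holm_adjust(raw)
    assert all(a >= r for a, r in zip(adj, raw))
    assert max(adj) <= 1.0
    assert adj[0] == pytest.approx(0.04)
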