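import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from afmse import riskstats as rs
from afmse.synthetic import SynthConfig, generate_cohort


@pytest.fixture(scope="module")
def cohort():
    return generate_cohort(SynthConfig(seed=42, n_patients=400)).table


class TestCha2ds2Vasc:
    @pytest.mark.parametrize("kwargs, expected", [
        # 70-year-old male with hypertension only: age 65-74 (1) + HTN (1)
        (dict(age=70, female=False, chf=False, hypertension=True,
              diabetes=False, stroke_tia=False, vascular=False), 2),
        (dict(age=30, female=False, chf=False, hypertension=False,
              diabetes=False, stroke_tia=False, vascular=False), 0),
        # 80-year-old female, prior stroke and every comorbidity: maximum 9
        (dict(age=80, female=True, chf=True, hypertension=True,
              diabetes=True, stroke_tia=True, vascular=True), 9),
        (dict(age=75, female=False, chf=False, hypertension=False,
              diabetes=False, stroke_tia=False, vascular=False), 2),
        (dict(age=64.9, female=True, chf=False, hypertension=False,
              diabetes=False, stroke_tia=False, vascular=False), 1),
    ])
    def test_known_scores(self, kwargs, expected):
        assert rs.cha2ds2_vasc(**kwargs) == expected

    def test_missing_component_raises(self):
        with pytest.raises(ValueError):
            rs.cha2ds2_vasc(age=float("nan"), female=False, chf=False,
                            hypertension=False, diabetes=False,
                            stroke_tia=False, vascular=False)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.floats(18, 100), *[st.booleans()] * 6)
    def test_score_always_in_range(self, age, f, c, h, d, s, v):
        score = rs.cha2ds2_vasc(age=age, female=f, chf=c, hypertension=h,
                                diabetes=d, stroke_tia=s, vascular=v)
        assert 0 <= score <= 9


class TestCompareGroups:
    def test_identical_groups_give_p_one(self):
        df = pd.DataFrame({"x": np.tile([1.0, 2.0, 3.0, 4.0], 2),
                           "event": [0] * 4 + [1] * 4})
        cmp_ = rs.compare_groups(df, "x")
        assert cmp_.p_value == pytest.approx(1.0)
        assert cmp_.means[0] == cmp_.means[1]

    def test_calibrated_group_offset_detected(self):
        # study-like sizes and moments: 22 vs 151, means 0.68 / 0.60
        hits = 0
        for seed in range(20):
            g = np.random.default_rng(seed)
            df = pd.DataFrame({
                "x": np.concatenate([g.normal(0.68, 0.15, 22),
                                     g.normal(0.60, 0.14, 151)]),
                "event": [1] * 22 + [0] * 151})
            hits += rs.compare_groups(df, "x").p_value < 0.05
        assert hits >= 11  # significant in the majority of seeds

    def test_categorical_dispatch_small_cells_uses_fisher(self):
        df = pd.DataFrame({"flag": [1, 0, 0, 0, 0] * 6,
                           "event": [1] * 5 + [0] * 25})
        cmp_ = rs.compare_groups(df, "flag")
        assert cmp_.kind == "categorical" and cmp_.test == "fisher_exact"

    def test_categorical_large_cells_uses_chi2(self, cohort):
        cmp_ = rs.compare_groups(cohort, "hypertension")
        assert cmp_.test == "chi2"

    def test_empty_group_rejected(self):
        df = pd.DataFrame({"x": [1.0, 2.0], "event": [0, 0]})
        with pytest.raises(ValueError):
            rs.compare_groups(df, "x")


class TestCorrelationMatrix:
    def test_self_and_negation(self, rng):
        x = rng.normal(size=60)
        df = pd.DataFrame({"x": x, "neg": -x, "y": rng.normal(size=60)})
        rho, p, stars = rs.correlation_matrix(df, ["x", "neg", "y"])
        assert rho.loc["x", "x"] == pytest.approx(1.0)
        assert rho.loc["x", "neg"] == pytest.approx(-1.0)
        assert stars.loc["x", "neg"] == "***"

    def test_constant_feature_flagged_nan(self, rng):
        df = pd.DataFrame({"x": rng.normal(size=30), "c": np.ones(30)})
        rho, _, stars = rs.correlation_matrix(df, ["x", "c"])
        assert np.isnan(rho.loc["x", "c"]) and stars.loc["x", "c"] == ""

    def test_too_few_records_rejected(self):
        with pytest.raises(ValueError):
            rs.correlation_matrix(pd.DataFrame({"x": [1, 2]}), ["x"])


class TestCovariateRegression:
    def test_independent_target_gives_near_zero_r2(self, cohort):
        df = cohort.copy()
        df["noise"] = np.random.default_rng(0).normal(size=len(df))
        fit = rs.covariate_regression(df, "noise",
                                      ["age", "female", "chf", "hypertension"])
        assert fit.rsquared < 0.03

    def test_recovers_constructed_sex_effect(self, cohort):
        g = np.random.default_rng(1)
        df = cohort.copy()
        df["target"] = 0.6 + 0.08 * df["female"] + g.normal(0, 0.1, len(df))
        fit = rs.covariate_regression(df, "target", ["age", "female", "diabetes"])
        lo, hi = fit.conf_int().loc["female"]
        assert lo < 0.08 < hi

    def test_collinear_design_rejected_with_names(self, cohort):
        df = cohort.copy()
        df["age_copy"] = df["age"]
        with pytest.raises(ValueError, match="age_copy"):
            rs.covariate_regression(df, "mean_en_vlf2", ["age", "age_copy"])


class TestCStatistic:
    def test_perfect_score_gives_auc_one(self):
        df = pd.DataFrame({"s": [0.1, 0.2, 0.8, 0.9], "event": [0, 0, 1, 1]})
        assert rs.c_statistic(df, "s").auc == 1.0

    def test_random_score_near_half_over_seeds(self):
        aucs = []
        for seed in range(30):
            g = np.random.default_rng(seed)
            df = pd.DataFrame({"s": g.normal(size=200),
                               "event": g.integers(0, 2, 200)})
            aucs.append(rs.c_statistic(df, "s").auc)
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.03)

    def test_negated_score_mirrors_auc(self, cohort):
        df = cohort.copy()
        df["neg"] = -df["mean_en_vlf2"]
        a = rs.c_statistic(df, "mean_en_vlf2").auc
        b = rs.c_statistic(df, "neg").auc
        assert a + b == pytest.approx(1.0)

    def test_ci_contains_auc(self, cohort):
        res = rs.c_statistic(cohort, "mean_en_vlf2")
        assert res.ci_low <= res.auc <= res.ci_high

    def test_single_class_rejected(self):
        df = pd.DataFrame({"s": [0.1, 0.2], "event": [0, 0]})
        with pytest.raises(ValueError):
            rs.c_statistic(df, "s")

    def test_identical_scores_compare_with_p_one(self, cohort):
        df = cohort.copy()
        df["dup"] = df["mean_en_vlf2"]
        assert rs.compare_c(df, "mean_en_vlf2", "dup") == pytest.approx(1.0)

    def test_informative_vs_noise_score_detected(self, cohort):
        df = cohort.copy()
        df["noise"] = np.random.default_rng(3).normal(size=len(df))
        p = rs.compare_c(df, "mean_en_vlf2", "noise")
        auc_f = rs.c_statistic(df, "mean_en_vlf2").auc
        assert auc_f > 0.6 and p < 0.05


class TestCoxFit:
    def test_hr_invariant_under_feature_rescaling(self, cohort):
        df = cohort.copy()
        df["scaled"] = df["mean_en_vlf2"] * 1234.5
        a = rs.cox_fit(df, "mean_en_vlf2")
        b = rs.cox_fit(df, "scaled")
        assert a.hr_per_sd == pytest.approx(b.hr_per_sd, rel=1e-6)

    def test_adjusted_fit_reports_adjusters(self, cohort):
        res = rs.cox_fit(cohort, "mean_en_vlf2",
                         adjusters=["age", "cha2ds2_vasc", "antithrombotic"])
        assert res.adjusters == ["age", "cha2ds2_vasc", "antithrombotic"]
        assert res.ci_low < res.hr_per_sd < res.ci_high

    def test_no_events_rejected(self, cohort):
        df = cohort.copy()
        df["event"] = 0
        with pytest.raises(ValueError):
            rs.cox_fit(df, "mean_en_vlf2")


class TestCumulativeIncidence:
    def test_no_events_gives_flat_zero_curves(self):
        df = pd.DataFrame({"mean_en_vlf2": np.linspace(0, 1, 10),
                           "follow_up_months": np.linspace(1, 50, 10),
                           "event": 0})
        ci = rs.cumulative_incidence(df)
        for curve in ci.curves.values():
            assert (curve.to_numpy() == 0).all()

    def test_nelson_aalen_matches_hand_enumeration(self):
        # 5 subjects, no censoring, events at t=1,2,3,4,5:
        # increments 1/5, 1/4, 1/3, 1/2, 1/1
        df = pd.DataFrame({"follow_up_months": [1.0, 2.0, 3.0, 4.0, 5.0],
                           "event": 1, "g": "all"})
        ci = rs.cumulative_incidence(df, group_by="g")
        curve = ci.curves["all"].iloc[:, 0]
        expected = np.cumsum([1 / 5, 1 / 4, 1 / 3, 1 / 2, 1 / 1])
        np.testing.assert_allclose(curve.loc[[1, 2, 3, 4, 5]].to_numpy(),
                                   expected, rtol=1e-10)

    def test_high_entropy_group_curve_dominates(self):
        hits = 0
        for seed in range(10):
            table = generate_cohort(SynthConfig(seed=seed, n_patients=600)).table
            ci = rs.cumulative_incidence(table)
            hi = ci.curves["high"].iloc[-1, 0]
            lo = ci.curves["low"].iloc[-1, 0]
            hits += (hi > lo) and (ci.logrank_p < 0.05)
        assert hits >= 8

    def test_empty_group_rejected(self, cohort):
        empty = pd.Series(["a"] * len(cohort), index=cohort.index)
        ci = rs.cumulative_incidence(cohort, group_by=empty)
        assert list(ci.curves) == ["a"]


class TestCrossValidate:
    def test_perfect_separation_scores_100_percent(self):
        df = pd.DataFrame({"s": np.r_[np.zeros(40), np.ones(40)],
                           "event": np.r_[np.zeros(40), np.ones(40)].astype(int)})
        cv = rs.cross_validate(df, "s", k=4, seed=0)
        assert cv.sensitivity == 1.0 and cv.specificity == 1.0

    def test_label_independent_score_near_chance(self):
        # leakage check: thresholds tuned on training folds only, so a
        # permuted (uninformative) score cannot beat chance systematically
        youden = []
        for seed in range(15):
            g = np.random.default_rng(seed)
            df = pd.DataFrame({"s": g.normal(size=300),
                               "event": g.permutation([1] * 60 + [0] * 240)})
            cv = rs.cross_validate(df, "s", k=4, seed=seed)
            youden.append(cv.sensitivity + cv.specificity - 1.0)
        assert abs(np.mean(youden)) < 0.1

    def test_too_few_events_rejected(self):
        df = pd.DataFrame({"s": np.arange(20.0),
                           "event": [1] * 2 + [0] * 18})
        with pytest.raises(ValueError):
            rs.cross_validate(df, "s", k=4)
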