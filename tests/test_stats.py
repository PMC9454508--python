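import math

import numpy as np
import pandas as pd
import pytest

from contexture.model import AnalysisConfig
from contexture.stats import (chi_square, cox_multivariate_backward,
                              cox_univariate, km_survival_at, logrank_test,
                              mann_whitney_u, round_half_away,
                              scenario_classify, spearman, subgroup_forest,
                              table_one, wilcoxon_signed_rank)


class TestMannWhitney:
    def test_symmetric_groups_p_one(self):
        assert mann_whitney_u([1, 2], [1, 2]).p_value == 1.0

    def test_fully_separated_groups_of_three(self):
        # enumeration of all 20 rank splits: only U=0 and U=9 are as extreme
        res = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(0.1)

    def test_shifted_normals_detected(self, rng):
        x = rng.normal(0, 1, 100)
        y = rng.normal(1.2, 1, 100)
        assert mann_whitney_u(x, y).p_value < 0.01

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])

    def test_exact_and_approximation_agree_at_boundary(self, rng):
        # n=8 per group sits at the exact/approximate switch
        import scipy.stats as st
        for _ in range(10):
            x = rng.normal(0, 1, 8)
            y = rng.normal(0.5, 1, 8)
            exact = mann_whitney_u(x, y).p_value
            approx = float(st.mannwhitneyu(
                x, y, alternative="two-sided", method="asymptotic",
                use_continuity=True).pvalue)
            assert abs(exact - approx) < 0.02


class TestWilcoxon:
    def test_antisymmetric_pair_p_one(self):
        assert wilcoxon_signed_rank([1, -1]).p_value == 1.0

    def test_all_positive_five(self):
        # all 32 sign patterns; only W+=0 and W+=15 are as extreme
        assert wilcoxon_signed_rank([1, 2, 3, 4, 5]).p_value \
            == pytest.approx(2 / 32)

    def test_zeros_dropped(self):
        res = wilcoxon_signed_rank([0, 0, 1, 2, 3, 4, 5])
        assert res.n == (5,)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([0.0, 0.0])

    def test_sign_flip_symmetry(self, rng):
        d = rng.normal(0.3, 1, 12)
        a = wilcoxon_signed_rank(d)
        b = wilcoxon_signed_rank(-d)
        assert a.p_value == pytest.approx(b.p_value)


class TestChiSquare:
    def test_balanced_table_is_null(self):
        res = chi_square([[10, 10], [10, 10]])
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_survival_table_from_printed_counts(self):
        # 2x2 of alive/dead by score group; Pearson without correction
        res = chi_square([[28, 15], [28, 4]])
        assert res.statistic == pytest.approx(4.86, abs=0.01)
        assert res.p_value == pytest.approx(0.027, abs=0.001)
        yates = chi_square([[28, 15], [28, 4]], correction=True)
        assert yates.p_value == pytest.approx(0.053, abs=0.001)

    def test_doubling_counts_doubles_statistic(self):
        t = np.array([[12, 5], [7, 9]])
        assert chi_square(2 * t).statistic == pytest.approx(
            2 * chi_square(t).statistic)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError):
            chi_square([[0, 0], [5, 3]])


class TestSpearman:
    def test_perfect_monotone(self):
        assert spearman([1, 2, 3, 4], [10, 20, 30, 40]).estimate == 1.0
        assert spearman([1, 2, 3, 4], [4, 3, 2, 1]).estimate == -1.0

    def test_hand_rank_formula_five_pairs(self):
        x = [1, 2, 3, 4, 5]
        y = [2, 1, 4, 3, 5]
        d2 = sum((a - b) ** 2 for a, b in zip(x, y))
        expected = 1 - 6 * d2 / (5 * 24)
        assert spearman(x, y).estimate == pytest.approx(expected)

    def test_constant_vector_flagged(self):
        res = spearman([1, 1, 1], [1, 2, 3])
        assert math.isnan(res.estimate)


class TestKaplanMeier:
    def test_no_events_full_survival(self):
        assert km_survival_at([70, 80, 90], [0, 0, 0], 60).km == 1.0

    def test_all_die_early(self):
        s = km_survival_at([1, 1, 1], [1, 1, 1], 60)
        assert s.km == 0.0 and s.crude == 0.0

    def test_product_limit_hand_example(self):
        # censored at 10, death at 20 (risk 3), censored at 30, death at 40
        # (risk 1): S(60) = (1 - 1/3)(1 - 1/1) = 0
        s = km_survival_at([10, 20, 30, 40], [0, 1, 0, 1], 60)
        assert s.km == pytest.approx(0.0)

    def test_km_equals_crude_without_early_censoring(self, rng):
        times = rng.uniform(61, 120, 30)
        events = rng.random(30) < 0.4
        deaths = rng.uniform(1, 59, 10)
        t = np.concatenate([times, deaths])
        e = np.concatenate([events, np.ones(10, bool)])
        # deaths before horizon all observed; censoring only after horizon
        s = km_survival_at(t, e, 60)
        assert s.km == pytest.approx(s.crude)


class TestLogrank:
    def test_identical_groups_null(self):
        times = [5, 10, 15, 20, 5, 10, 15, 20]
        events = [1, 1, 0, 1, 1, 1, 0, 1]
        groups = [0, 0, 0, 0, 1, 1, 1, 1]
        res = logrank_test(times, events, groups)
        assert res.statistic == pytest.approx(0.0, abs=1e-9)

    def test_detects_early_deaths_in_one_group(self, rng):
        t0 = rng.exponential(10, 50)
        t1 = rng.exponential(60, 50)
        times = np.concatenate([t0, t1])
        events = np.ones(100, bool)
        groups = np.repeat([0, 1], 50)
        assert logrank_test(times, events, groups).p_value < 0.01

    def test_invariant_to_group_relabeling(self, rng):
        times = rng.exponential(30, 40)
        events = rng.random(40) < 0.7
        groups = rng.integers(0, 2, 40)
        a = logrank_test(times, events, groups)
        b = logrank_test(times, events, 1 - groups)
        assert a.statistic == pytest.approx(b.statistic)

    def test_no_events_rejected(self):
        with pytest.raises(ValueError):
            logrank_test([5, 10], [0, 0], [0, 1])


def surv_frame(rng, n=200, beta=0.0):
    x = rng.integers(0, 2, n).astype(float)
    t = rng.exponential(1 / (0.01 * np.exp(beta * x)))
    c = rng.uniform(0, 120, n)
    return pd.DataFrame({"os_months": np.minimum(t, c), "os_event": t <= c,
                         "x": x})


class TestCox:
    def test_scaling_covariate_rescales_beta(self, rng):
        df = surv_frame(rng, 300, beta=-0.8)
        df["x"] += rng.normal(0, 0.1, len(df))  # make it continuous
        a = cox_univariate(df, "x")
        df["x10"] = df["x"] * 10
        b = cox_univariate(df, "x10")
        assert a.coef == pytest.approx(b.coef * 10, rel=1e-6)

    def test_hr_recovery_binary_covariate(self, rng):
        hrs = []
        for _ in range(30):
            df = surv_frame(rng, 300, beta=math.log(0.3))
            hrs.append(cox_univariate(df, "x").hr)
        assert 0.25 <= float(np.mean(hrs)) <= 0.36

    def test_null_covariate_ci_covers_one(self, rng):
        cover = 0
        for _ in range(60):
            df = surv_frame(rng, 150, beta=0.0)
            res = cox_univariate(df, "x")
            cover += res.ci_low <= 1.0 <= res.ci_high
        assert cover / 60 >= 0.90

    def test_degenerate_fit_flagged_not_raised(self):
        df = pd.DataFrame({"os_months": [10.0, 20, 30, 40],
                           "os_event": [1, 1, 0, 0],
                           "x": [1.0, 1.0, 0.0, 0.0]})  # separation-ish
        res = cox_univariate(df, "x")
        assert isinstance(res.converged, bool)  # never raises


class TestBackwardElimination:
    def test_single_candidate_equals_univariate(self, rng):
        df = surv_frame(rng, 300, beta=-1.2)
        uni = cox_univariate(df, "x")
        be = cox_multivariate_backward(df, ["x"])
        assert be.retained == ["x"]
        assert be.results[0].hr == pytest.approx(uni.hr, rel=1e-6)

    def test_two_strong_predictors_both_retained(self, rng):
        n = 300
        x1 = rng.integers(0, 2, n).astype(float)
        x2 = rng.integers(0, 2, n).astype(float)
        t = rng.exponential(1 / (0.01 * np.exp(-1.0 * x1 + 1.0 * x2)))
        c = rng.uniform(0, 200, n)
        df = pd.DataFrame({"os_months": np.minimum(t, c),
                           "os_event": t <= c, "x1": x1, "x2": x2})
        be = cox_multivariate_backward(df, ["x1", "x2"])
        assert set(be.retained) == {"x1", "x2"}

    def test_pure_noise_mostly_eliminated(self, rng):
        # a noise candidate enters only when its univariate p < 0.1, so the
        # empty-model rate should sit near 0.9**5 ~ 0.59 for 5 candidates
        empty = 0
        retained_total = 0
        reps = 20
        for _ in range(reps):
            n = 120
            df = surv_frame(rng, n, beta=0.0)
            for j in range(5):
                df[f"z{j}"] = rng.normal(0, 1, n)
            be = cox_multivariate_backward(df, [f"z{j}" for j in range(5)])
            empty += not be.retained
            retained_total += len(be.retained)
        assert empty / reps >= 0.40
        assert retained_total / reps <= 1.5


class TestScenarioClassify:
    def test_score_low_is_scenario_one_regardless_of_tfh(self):
        assert scenario_classify("low", 0.9, 0.2) == 1
        assert scenario_classify("low", float("nan"), 0.2) == 1

    def test_score_high_splits_on_tfh_median(self):
        assert scenario_classify("high", 0.1, 0.2) == 2
        assert scenario_classify("high", 0.5, 0.2) == 3

    def test_high_score_undefined_tfh_unclassifiable(self):
        assert scenario_classify("high", float("nan"), 0.2) is None

    def test_labels_partition_defined_cohort(self, rng):
        tfh = pd.Series(rng.uniform(0, 0.5, 30))
        med = float(tfh.median())
        scores = np.where(rng.random(30) < 0.5, "high", "low")
        labels = [scenario_classify(s, f, med) for s, f in zip(scores, tfh)]
        assert all(lab in (1, 2, 3) for lab in labels)
        assert len(labels) == 30


class TestSubgroupForest:
    def test_strata_partition_and_flags(self, rng):
        n = 120
        df = surv_frame(rng, n, beta=-1.0)
        df["cd20_cluster_score"] = np.where(df["x"] > 0, "high", "low")
        df["strat"] = rng.normal(0, 1, n)
        forest = subgroup_forest(df, "cd20_cluster_score", ["strat"])
        assert forest["n"].sum() == n
        assert set(forest["stratum"]) == {"low", "high"}

    def test_stratum_without_events_non_estimable(self):
        df = pd.DataFrame({
            "os_months": [10.0, 20, 30, 40, 50, 60],
            "os_event": [0, 0, 0, 1, 1, 1],
            "cd20_cluster_score": ["high", "low", "high", "low", "high", "low"],
            "strat": [0.0, 0.0, 0.0, 1.0, 1.0, 1.0],
        })
        forest = subgroup_forest(df, "cd20_cluster_score", ["strat"])
        low = forest[forest["stratum"] == "low"].iloc[0]
        assert not low["estimable"]


class TestTableOne:
    def test_rounding_half_away_from_zero(self):
        assert round_half_away(87.5) == 88
        assert round_half_away(65.1) == 65
        assert round_half_away(44.19) == 44

    def test_percentages_and_pvalues(self):
        rng = np.random.default_rng(4)
        n = 75
        clinical = pd.DataFrame({
            "age": rng.normal(62, 10, n).round(),
            "sex": rng.choice(["male", "female"], n),
            "pT": rng.choice(["pT1", "pT2"], n),
            "pN": rng.choice(["pN0", "pN1"], n, p=[0.9, 0.1]),
            "pStage": rng.choice(["1", "2"], n),
            "grade": rng.choice(["well", "moderate", "poor"], n),
            "lvi": rng.random(n) < 0.1,
            "os_months": rng.uniform(1, 120, n),
            "os_event": rng.random(n) < 0.3,
        }, index=[f"P{i}" for i in range(n)])
        group = pd.Series(np.where(np.arange(n) < 43, "low", "high"),
                          index=clinical.index)
        table, pvals = table_one(clinical, group)
        assert "age" in pvals and 0 <= pvals["sex"] <= 1
        # counts per variable per group sum to the group size
        sex = table[(table["variable"] == "sex") & (table["group"] == "low")]
        assert sex["count"].sum() == 43

    def test_empty_group_no_division_error(self):
        clinical = pd.DataFrame({
            "age": [60.0, 70.0], "sex": ["male", "female"],
            "pT": ["pT1", "pT2"], "pN": ["pN0", "pN0"],
            "pStage": ["1", "1"], "grade": ["well", "poor"],
            "lvi": [False, False], "os_months": [60.0, 70.0],
            "os_event": [0, 1],
        }, index=["P1", "P2"])
        group = pd.Series(["low", "low"], index=clinical.index)
        table, pvals = table_one(clinical, group)
        assert (table["group"] == "low").all()
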