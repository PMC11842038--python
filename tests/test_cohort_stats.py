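"""Correlation gating, mixed-design t-test, residualisation, regression
diagnostics, commonality decomposition and piecewise growth fits."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from efrpipe import cohort_stats as cs


class TestCorrelationAuto:
    def test_gaussian_pair_uses_pearson(self, rng):
        x = rng.standard_normal(60)
        y = 0.5 * x + rng.standard_normal(60)
        rep = cs.correlation_auto(x, y)
        assert rep.method == "pearson"
        assert rep.estimate == pytest.approx(stats.pearsonr(x, y)[0])

    def test_skewed_variable_uses_spearman(self, rng):
        x = rng.standard_normal(100)
        y = np.exp(3 * rng.standard_normal(100))
        assert cs.correlation_auto(x, y).method == "spearman"

    def test_monotone_nonlinear_pair_gives_rho_one(self, rng):
        x = np.exp(rng.standard_normal(50))
        rep = cs.correlation_auto(x, x**3)
        assert rep.method == "spearman"
        assert rep.estimate == pytest.approx(1.0, abs=1e-12)

    def test_constant_input_raises(self):
        with pytest.raises(ValueError):
            cs.correlation_auto(np.ones(10), np.arange(10.0))


def test_bonferroni_scales_and_caps():
    assert cs.bonferroni(0.01, 6) == pytest.approx(0.06)
    assert cs.bonferroni(0.3, 18) == 1.0
    assert cs.bonferroni(0.2, 1) == pytest.approx(0.2)
    p = np.array([0.001, 0.02, 0.7])
    adj = cs.bonferroni(p, 10)
    assert np.all(np.diff(adj[np.argsort(p)]) >= 0)  # monotone
    assert np.all((adj >= 0) & (adj <= 1))


class TestPosTtest:
    def test_paired_only_limit_matches_paired_t(self, rng):
        pre = rng.standard_normal(12)
        post = pre + 0.4 + 0.3 * rng.standard_normal(12)
        t, df, p = cs.pos_ttest(pre, post, variance_mode="unequal")
        t_ref, p_ref = stats.ttest_rel(pre, post)
        assert t == pytest.approx(t_ref, abs=1e-8)
        assert df == pytest.approx(11)
        assert p == pytest.approx(p_ref, abs=1e-8)

    def test_independent_only_limit_matches_student_t(self, rng):
        a = rng.standard_normal(14)
        b = rng.standard_normal(9) + 0.5
        t, df, p = cs.pos_ttest([], [], a, b, variance_mode="equal")
        t_ref, p_ref = stats.ttest_ind(a, b)
        assert t == pytest.approx(t_ref, abs=1e-8)
        assert df == pytest.approx(21)
        assert p == pytest.approx(p_ref, abs=1e-8)

    def test_mixed_design_df_formula(self, rng):
        # equal-variance df: (n12-1) + (na+nb+n12-1)/(na+nb+2 n12)*(na+nb)
        pre, post = rng.standard_normal(3), rng.standard_normal(3)
        a, b = rng.standard_normal(11), rng.standard_normal(4)
        _, df, _ = cs.pos_ttest(pre, post, a, b, "equal")
        assert df == pytest.approx(2 + 17 / 21 * 15)

    def test_empty_inputs_raise(self):
        with pytest.raises(ValueError):
            cs.pos_ttest([], [], [1.0], [])


class TestResidualize:
    def test_independent_y_residuals_are_centered_y(self, rng):
        y = rng.standard_normal(30)
        x = np.arange(30.0)
        res = cs.residualize(y, x)
        # mean removed; orthogonal to x
        assert abs(res.mean()) < 1e-10
        assert abs(np.dot(res, x - x.mean())) < 1e-8

    def test_perfect_fit_gives_zero_residuals(self):
        x = np.arange(10.0)
        res = cs.residualize(2 * x, x)
        np.testing.assert_allclose(res, 0.0, atol=1e-10)

    def test_hand_computed_five_point_example(self):
        # x=[0..4], y=[1,3,4,9,10]: slope 24/10=2.4, intercept 0.6,
        # fitted [0.6, 3.0, 5.4, 7.8, 10.2], residuals worked out by hand
        res = cs.residualize([1, 3, 4, 9, 10], [0, 1, 2, 3, 4])
        np.testing.assert_allclose(res, [0.4, 0.0, -1.4, 1.2, -0.2],
                                   atol=1e-10)

    def test_constant_x_raises(self):
        with pytest.raises(ValueError):
            cs.residualize([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])


class TestLinearModels:
    def test_orthogonal_standardized_predictors_have_unit_vif(self):
        n = 64
        x1 = np.tile([1.0, -1.0], n // 2)
        x2 = np.repeat([1.0, -1.0], n // 2)
        y = x1 + 0.5 * x2 + 0.1 * np.random.default_rng(0).standard_normal(n)
        rep = cs.fit_linear_models(y, pd.DataFrame({"x1": x1, "x2": x2}))
        for v in rep.vif.values():
            assert v == pytest.approx(1.0, abs=1e-10)
        assert rep.adj_r_squared <= rep.r_squared

    def test_coefficient_recovery_within_3se(self, rng):
        hits = 0
        for _ in range(100):
            x1 = rng.standard_normal(200)
            x2 = rng.standard_normal(200)
            y = 1.5 * x1 - 2.0 * x2 + rng.standard_normal(200)
            rep = cs.fit_linear_models(y, pd.DataFrame({"x1": x1, "x2": x2}))
            ok = (abs(rep.params["x1"] - 1.5) < 3 * rep.bse["x1"]
                  and abs(rep.params["x2"] + 2.0) < 3 * rep.bse["x2"])
            hits += ok
        assert hits >= 95  # 3 SE ~ 99.7% coverage per coefficient

    def test_null_interaction_p_uniform(self, rng):
        pvals = []
        for _ in range(1000):
            x1 = rng.standard_normal(50)
            x2 = rng.standard_normal(50)
            y = x1 + x2 + rng.standard_normal(50)
            rep = cs.fit_linear_models(y, pd.DataFrame({"a": x1, "b": x2}),
                                       include_interaction=True)
            pvals.append(rep.pvalues["a:b"])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_rank_deficiency_raises(self, rng):
        x = rng.standard_normal(20)
        with pytest.raises(ValueError):
            cs.fit_linear_models(x, pd.DataFrame({"a": x, "b": 2 * x}))


class TestCommonality:
    def test_orthogonal_predictors_share_nothing(self):
        n = 40
        x1 = np.tile([1.0, -1.0], n // 2)
        x2 = np.repeat([1.0, -1.0], n // 2)
        y = x1 + 0.5 * x2
        dec = cs.commonality(y, pd.DataFrame({"x1": x1, "x2": x2}))
        assert dec.common[("x1", "x2")] == pytest.approx(0.0, abs=1e-10)
        # unique contributions equal single-predictor R^2
        r2_1 = np.corrcoef(y, x1)[0, 1] ** 2
        assert dec.unique["x1"] == pytest.approx(r2_1, abs=1e-10)

    def test_duplicated_predictor_is_all_common(self, rng):
        x = rng.standard_normal(50)
        y = x + 0.3 * rng.standard_normal(50)
        dec = cs.commonality(y, pd.DataFrame({"a": x, "b": x.copy()}))
        assert dec.unique["a"] == pytest.approx(0.0, abs=1e-6)
        assert dec.unique["b"] == pytest.approx(0.0, abs=1e-6)
        assert dec.common[("a", "b")] == pytest.approx(dec.total_r_squared,
                                                       abs=1e-6)

    def test_components_match_brute_force_subset_r2(self, rng):
        x1 = rng.standard_normal(80)
        x2 = 0.6 * x1 + rng.standard_normal(80)
        y = x1 + x2 + rng.standard_normal(80)

        def r2(*cols):
            X = np.column_stack([np.ones(80)] + list(cols))
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            resid = y - X @ beta
            return 1 - resid.var() / y.var()

        dec = cs.commonality(y, pd.DataFrame({"x1": x1, "x2": x2}))
        r1, r2_, r12 = r2(x1), r2(x2), r2(x1, x2)
        assert dec.unique["x1"] == pytest.approx(r12 - r2_, abs=1e-10)
        assert dec.unique["x2"] == pytest.approx(r12 - r1, abs=1e-10)
        assert dec.common[("x1", "x2")] == pytest.approx(r1 + r2_ - r12,
                                                         abs=1e-10)

    def test_three_predictor_conservation(self, rng):
        X = pd.DataFrame(rng.standard_normal((60, 3)), columns=list("abc"))
        y = X.sum(axis=1) + rng.standard_normal(60)
        dec = cs.commonality(y, X)
        assert sum(dec.components.values()) == pytest.approx(
            dec.total_r_squared, abs=1e-10)
        assert sum(dec.percentages().values()) == pytest.approx(100.0,
                                                                abs=1e-6)


def test_db_to_microvolt():
    assert cs.db_to_microvolt(0.0) == 1.0
    assert cs.db_to_microvolt(-20.0) == pytest.approx(0.1)
    assert cs.db_to_microvolt(6.0206) == pytest.approx(2.0, abs=1e-4)


class TestPiecewiseGrowth:
    def test_exact_two_segment_recovery(self):
        x = np.arange(20.0, 85.0, 5.0)
        y = np.where(x < 60, 0.01 * (x - 60) + 0.08, 0.002 * (x - 60) + 0.08)
        lo, hi, knee = cs.fit_piecewise_growth(x, y)
        assert knee == pytest.approx(60.0)
        assert lo == pytest.approx(0.01, abs=1e-8)
        assert hi == pytest.approx(0.002, abs=1e-8)

    def test_straight_line_equal_slopes(self):
        x = np.arange(20.0, 85.0, 5.0)
        lo, hi, _ = cs.fit_piecewise_growth(x, 0.003 * x + 0.1, knee=60.0)
        assert lo == pytest.approx(0.003, abs=1e-8)
        assert hi == pytest.approx(0.003, abs=1e-8)

    def test_noisy_upper_slope_recovered_within_20pct(self, rng):
        x = np.arange(20.0, 85.0, 5.0)
        truth = np.where(x < 60, 0.01 * (x - 60) + 0.08,
                         0.002 * (x - 60) + 0.08)
        slopes = []
        for _ in range(50):
            y = truth + 0.005 * rng.standard_normal(len(x))
            _, hi, _ = cs.fit_piecewise_growth(x, y, knee=60.0)
            slopes.append(hi)
        assert np.mean(slopes) == pytest.approx(0.002, rel=0.2)

    def test_insufficient_side_points_raise(self):
        with pytest.raises(ValueError):
            cs.fit_piecewise_growth([1, 2, 3], [1, 2, 3], knee=2.0)


class TestGroupSummary:
    def test_identical_groups_not_significant(self):
        base = np.arange(10.0)
        df = pd.DataFrame({"group": ["a"] * 10 + ["b"] * 10,
                           "v": np.r_[base, base]})
        desc, tests = cs.group_summary(df, ["v"])
        assert tests.loc[0, "t"] == pytest.approx(0.0, abs=1e-12)
        assert tests.loc[0, "p_adj"] == 1.0

    def test_power_against_closed_form(self, rng):
        # one-sided shift of 0.5 SD, n=50/group, alpha=.05 two-sided
        n, delta, alpha, reps = 50, 0.5, 0.05, 400
        ncp = delta * np.sqrt(n / 2)
        df_t = 2 * n - 2
        tcrit = stats.t.ppf(1 - alpha / 2, df_t)
        power = (1 - stats.nct.cdf(tcrit, df_t, ncp)
                 + stats.nct.cdf(-tcrit, df_t, ncp))
        hits = 0
        for _ in range(reps):
            df = pd.DataFrame({
                "group": ["a"] * n + ["b"] * n,
                "v": np.r_[rng.standard_normal(n),
                           rng.standard_normal(n) + delta]})
            _, tests = cs.group_summary(df, ["v"])
            hits += tests.loc[0, "p"] < alpha
        se = np.sqrt(power * (1 - power) / reps)
        assert hits / reps == pytest.approx(power, abs=3 * se)

    def test_empty_group_raises(self):
        df = pd.DataFrame({"group": ["a", "a", "b"], "v": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError):
            cs.group_summary(df, ["v"])
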