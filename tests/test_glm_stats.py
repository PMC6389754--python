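"""Grand-average statistics: OLS substrate, Type III ANCOVA, contrasts,
effect sizes, assumption checks, and the cohort-table tests."""

import numpy as np
import pandas as pd
import pytest

from alphashift import glm_stats as gs


@pytest.fixture(scope="module")
def cohort_frame():
    """102-subject frame with known three-group structure."""
    rng = np.random.default_rng(5)
    groups = np.repeat(["HS", "GSC", "PSC"], [39, 25, 38])
    shift = rng.normal(0, 0.5, 102) + np.select(
        [groups == "HS", groups == "GSC"], [-0.3, -0.2], 0.3)
    return pd.DataFrame({
        "group": groups, "shift": shift,
        "age": rng.normal(34, 11, 102).clip(18),
        "gender": rng.choice(["F", "M"], 102),
    })


class TestFitLinearModel:
    def test_exact_recovery_zero_noise(self, rng):
        X = pd.DataFrame(rng.normal(size=(40, 3)), columns=list("abc"))
        beta = np.array([1.5, -2.0, 0.25])
        fit = gs.fit_linear_model(X.to_numpy() @ beta, X)
        np.testing.assert_allclose(fit.coef, beta, atol=1e-10)

    def test_intercept_only_gives_mean(self, rng):
        y = rng.normal(size=25)
        X = pd.DataFrame({"intercept": np.ones(25)})
        fit = gs.fit_linear_model(y, X)
        assert fit.coef[0] == pytest.approx(y.mean(), abs=1e-12)

    def test_matches_normal_equations_oracle(self, rng):
        X = pd.DataFrame(rng.normal(size=(60, 4)),
                         columns=["a", "b", "c", "d"])
        y = rng.normal(size=60)
        fit = gs.fit_linear_model(y, X)
        Xm = X.to_numpy()
        beta_oracle = np.linalg.solve(Xm.T @ Xm, Xm.T @ y)
        np.testing.assert_allclose(fit.coef, beta_oracle, atol=1e-8)
        # residuals orthogonal to design columns
        assert np.abs(Xm.T @ fit.residuals).max() < 1e-8

    def test_rank_deficiency_names_columns(self, rng):
        X = pd.DataFrame({"a": rng.normal(size=30)})
        X["b"] = 2 * X["a"]
        with pytest.raises(ValueError, match="collinear"):
            gs.fit_linear_model(rng.normal(size=30), X)


class TestAncova:
    def test_oneway_df_den_matches_model_spec(self, cohort_frame):
        res = gs.ancova_oneway(cohort_frame["shift"], cohort_frame["group"],
                               cohort_frame["age"], cohort_frame["gender"])
        assert (res.df_num, res.df_den) == (2, 97)

    def test_oneway_agrees_with_statsmodels_type3(self, cohort_frame):
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm
        df = cohort_frame.copy()
        df["gender_num"] = np.where(df["gender"] == "F", 1.0, -1.0)
        fit = smf.ols("shift ~ C(group, Sum) + age + gender_num",
                      data=df).fit()
        tab = anova_lm(fit, typ=3)
        row = tab.loc["C(group, Sum)"]
        res = gs.ancova_oneway(df["shift"], df["group"], df["age"],
                               df["gender"])
        assert res.F == pytest.approx(row["F"], rel=1e-8)
        assert res.p == pytest.approx(row["PR(>F)"], rel=1e-6)

    def test_eta_squared_saturates_at_one(self):
        groups = np.repeat(["A", "B", "C"], 20)
        shift = np.select([groups == "A", groups == "B"], [1.0, 2.0], 3.0)
        shift = shift + np.random.default_rng(0).normal(0, 1e-9, 60)
        age = np.tile(np.arange(20), 3) * 1e-9 + 30  # orthogonal covariate
        gender = np.tile(["F", "M"], 30)
        res = gs.ancova_oneway(shift, groups, age, gender)
        assert res.eta_squared == pytest.approx(1.0, abs=1e-6)

    def test_oneway_type_i_error_calibrated(self):
        """Null simulation: rejection rate at alpha=.05 inside the
        binomial 95% CI."""
        rng = np.random.default_rng(77)
        n_reps, rejections = 2000, 0
        groups = np.repeat(["A", "B", "C"], [20, 20, 20])
        gender = np.tile(["F", "M"], 30)
        for _ in range(n_reps):
            y = rng.normal(size=60)
            age = rng.normal(35, 10, 60)
            res = gs.ancova_oneway(y, groups, age, gender)
            rejections += res.p < 0.05
        rate = rejections / n_reps
        half = 1.96 * np.sqrt(0.05 * 0.95 / n_reps)
        assert abs(rate - 0.05) < half + 1e-12

    def test_covariate_centering_invariance(self, cohort_frame):
        res1 = gs.ancova_oneway(cohort_frame["shift"], cohort_frame["group"],
                                cohort_frame["age"], cohort_frame["gender"])
        res2 = gs.ancova_oneway(cohort_frame["shift"], cohort_frame["group"],
                                cohort_frame["age"] - 40,
                                cohort_frame["gender"])
        assert res1.F == pytest.approx(res2.F, rel=1e-10)

    def test_factorial_reports_three_effects_with_shared_df(self):
        rng = np.random.default_rng(8)
        n = 63
        syn = rng.choice(["FE", "IGE"], n)
        ctl = rng.choice(["GSC", "PSC"], n)
        y = rng.normal(size=n)
        res = gs.ancova_factorial(y, syn, ctl, rng.normal(35, 10, n),
                                  rng.choice(["F", "M"], n),
                                  rng.gamma(2, 0.7, n))
        names = [r.effect_name for r in res]
        assert names == ["syndrome", "control", "syndrome:control"]
        assert all(r.df_den == n - 7 for r in res)

    def test_factorial_detects_pure_interaction(self):
        rng = np.random.default_rng(9)
        n = 80
        syn = np.repeat(["FE", "IGE"], 40)
        ctl = np.tile(np.repeat(["GSC", "PSC"], 20), 2)
        y = np.where((syn == "FE") == (ctl == "GSC"), 1.0, -1.0) \
            + rng.normal(0, 0.5, n)
        res = gs.ancova_factorial(y, syn, ctl, rng.normal(35, 10, n),
                                  rng.choice(["F", "M"], n),
                                  rng.gamma(2, 0.7, n))
        F = {r.effect_name: r.F for r in res}
        assert F["syndrome:control"] > max(F["syndrome"], F["control"])

    def test_factorial_rejects_empty_cell(self):
        syn = np.repeat(["FE", "IGE"], 10)
        ctl = np.repeat(["GSC", "PSC"], 10)  # FE only GSC, IGE only PSC
        with pytest.raises(ValueError, match="cell"):
            gs.ancova_factorial(np.zeros(20), syn, ctl, np.arange(20),
                                np.tile(["F", "M"], 10), np.ones(20))


class TestPooledT:
    @pytest.mark.parametrize("a,b,t_expected,df_expected", [
        # printed clinical-table summaries: lamotrigine, levetiracetam,
        # valproate dosages (mean, sd, n)
        ((350, 91, 10), (242, 120, 12), 2.3, 20),
        ((1500, 595, 7), (1550, 934, 11), -0.13, 16),
        ((838, 307, 8), (1000, 531, 10), -0.77, 16),
    ])
    def test_summary_t_matches_printed_values(self, a, b, t_expected,
                                              df_expected):
        res = gs.pooled_t(a, b)
        assert res.df == df_expected
        assert res.t == pytest.approx(t_expected, abs=0.05)

    def test_identical_samples_give_zero(self, rng):
        x = rng.normal(size=15)
        res = gs.pooled_t(x, x.copy())
        assert res.t == 0.0

    def test_raw_equals_summary(self, rng):
        a = rng.normal(0, 1, 14)
        b = rng.normal(0.4, 1.3, 19)
        res_raw = gs.pooled_t(a, b)
        res_sum = gs.pooled_t((a.mean(), a.std(ddof=1), len(a)),
                              (b.mean(), b.std(ddof=1), len(b)))
        assert res_raw.t == res_sum.t
        assert res_raw.p == res_sum.p
        assert res_raw.g == pytest.approx(res_sum.g, abs=1e-12)

    def test_degenerate_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            gs.pooled_t(np.ones(5), np.zeros(5))


class TestHedgesG:
    def test_equal_means_give_zero(self, rng):
        x = rng.normal(size=30)
        g, _ = gs.hedges_g(x, x.copy(), n_boot=100, seed=0)
        assert g == 0.0

    def test_large_n_limit(self, rng):
        a = rng.normal(1, 1, 4000)
        b = rng.normal(0, 1, 4000)
        g, ci = gs.hedges_g(a, b, n_boot=200, seed=1)
        assert g == pytest.approx(1.0, abs=0.1)
        assert ci[0] < g < ci[1]

    def test_matches_textbook_formula_and_pingouin(self, rng):
        import pingouin
        for _ in range(5):
            a = rng.normal(0, 1, 12)
            b = rng.normal(0.5, 1.5, 17)
            g, _ = gs.hedges_g(a, b, n_boot=10, seed=0)
            # independent textbook implementation
            sp = np.sqrt(((len(a) - 1) * a.var(ddof=1)
                          + (len(b) - 1) * b.var(ddof=1))
                         / (len(a) + len(b) - 2))
            d = (a.mean() - b.mean()) / sp
            expected = d * (1 - 3 / (4 * (len(a) + len(b)) - 9))
            assert g == pytest.approx(expected, abs=1e-10)
            assert g == pytest.approx(
                pingouin.compute_effsize(a, b, eftype="hedges"), abs=1e-3)


class TestAssumptionChecks:
    def test_levene_detects_inflated_variance(self):
        rng = np.random.default_rng(3)
        shift = np.concatenate([rng.normal(0, 1, 30),
                                rng.normal(0, 10, 30)])
        group = np.repeat(["A", "B"], 30)
        W, p = gs.levene_test(shift, group)
        assert p < 0.05

    def test_levene_type_i_error_calibrated(self):
        # mean-centered Levene is asymptotically calibrated (and known to
        # be mildly liberal in very small groups); check at n = 60/group
        rng = np.random.default_rng(4)
        n_reps, rej = 2000, 0
        group = np.repeat(["A", "B", "C"], 60)
        for _ in range(n_reps):
            _, p = gs.levene_test(rng.normal(size=180), group)
            rej += p < 0.05
        half = 1.96 * np.sqrt(0.05 * 0.95 / n_reps)
        assert abs(rej / n_reps - 0.05) < half

    def test_parallel_slopes_give_near_zero_f(self):
        rng = np.random.default_rng(6)
        cov = rng.normal(size=45)
        group = np.repeat(["A", "B", "C"], 15)
        y = 2.0 * cov + np.select([group == "A", group == "B"],
                                  [0.0, 1.0], 2.0)
        F, p = gs.slope_homogeneity(y, group, cov)
        assert F == pytest.approx(0.0, abs=1e-12)

    def test_shapiro_wraps_residual_normality(self, rng):
        W, p = gs.normality_check(rng.normal(size=80))
        assert 0 < p <= 1 and 0 < W <= 1


class TestCategoricalTests:
    def test_sex_by_group_chi2_matches_printed_value(self):
        # female/male counts per cohort group
        table = [[19, 15, 19], [20, 10, 19]]
        chi2, df, p = gs.chi_square_independence(table)
        assert chi2 == pytest.approx(0.87, abs=0.005)
        assert df == 2

    def test_fe_syndrome_chi2_matches_printed_value(self):
        table = [[10, 27], [15, 11]]  # FE / non-FE x GSC / PSC
        chi2, df, p = gs.chi_square_independence(table)
        assert chi2 == pytest.approx(6.00, abs=0.005)
        assert df == 1

    def test_identical_row_proportions_give_zero(self):
        chi2, _, p = gs.chi_square_independence([[10, 20], [5, 10]])
        assert chi2 == pytest.approx(0.0, abs=1e-12)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            gs.chi_square_independence([[0, 0], [3, 4]])

    def test_fisher_exact_diagonal_table(self):
        # enumeration oracle: fixed margins 5/5, only the observed table
        # and its transpose are as extreme; p = 2 / C(10,5)
        assert gs.fisher_exact([[5, 0], [0, 5]]) == pytest.approx(2 / 252,
                                                                  abs=1e-10)

    def test_mann_whitney_identical_samples(self, rng):
        x = rng.normal(size=12)
        U, p = gs.mann_whitney_u(x, x.copy())
        assert U == pytest.approx(12 * 12 / 2)

    def test_kruskal_null_calibration(self):
        rng = np.random.default_rng(12)
        rej = 0
        n_reps = 2000
        for _ in range(n_reps):
            samples = [rng.normal(size=15) for _ in range(3)]
            _, p = gs.kruskal_wallis(samples)
            rej += p < 0.05
        half = 1.96 * np.sqrt(0.05 * 0.95 / n_reps)
        assert abs(rej / n_reps - 0.05) < half


class TestShiftSeizureCorrelation:
    def test_monotone_relation_gives_rho_one(self):
        counts = np.arange(20)
        shift = counts ** 2 + 1.0
        rho, p = gs.shift_seizure_correlation(shift, counts, n_perm=500,
                                              seed=0)
        assert rho == pytest.approx(1.0)
        assert p < 0.01

    def test_independent_vectors_give_small_rho(self):
        rng = np.random.default_rng(13)
        rho, p = gs.shift_seizure_correlation(rng.normal(size=200),
                                              rng.poisson(5, 200),
                                              n_perm=500, seed=1)
        assert abs(rho) < 0.2
        assert p > 0.01

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            gs.shift_seizure_correlation(np.ones(10), np.arange(10))
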