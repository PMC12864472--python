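"""Oracle checks for the statistical kernel.

Independent oracles: explicit normal-equations/pseudoinverse algebra,
statsmodels OLS, hypergeometric enumeration for Fisher's exact test,
the recursive first-order partial-correlation formula (plus pingouin),
and exhaustive permutation enumeration at n = 5.
"""

import itertools

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, settings, strategies as st
from scipy import stats

from tractstats.errors import (
    DegenerateDataError,
    SingularDesignError,
    TractStatsError,
)
from tractstats.linmod import (
    DesignMatrix,
    PermutationConfig,
    build_design,
    fisher_exact_2x2,
    maxstat_correct,
    ols_fit,
    one_sample_t,
    one_sample_t_from_summary,
    partial_r2,
    perm_null_ts,
    perm_pvalue,
    permute_term,
    signflip_null_ts,
    two_sample_t_from_summary,
    two_sample_t_pooled,
)


def random_design(rng, n=30, k=4):
    X = np.column_stack([np.ones(n), rng.standard_normal((n, k - 1))])
    return DesignMatrix(["intercept"] + [f"x{i}" for i in range(1, k)], X)


class TestOLS:
    def test_matches_pseudoinverse_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            X = random_design(rng)
            y = rng.standard_normal(30)
            fit = ols_fit(X, y)
            beta_o = np.linalg.pinv(X.matrix) @ y
            resid = y - X.matrix @ beta_o
            df = 30 - 4
            sigma2 = resid @ resid / df
            se_o = np.sqrt(np.diag(
                sigma2 * np.linalg.inv(X.matrix.T @ X.matrix)))
            np.testing.assert_allclose(fit.beta, beta_o, rtol=1e-10)
            np.testing.assert_allclose(fit.se, se_o, rtol=1e-10)
            np.testing.assert_allclose(fit.t, beta_o / se_o, rtol=1e-10)
            assert fit.df == df

    def test_matches_statsmodels(self):
        rng = np.random.default_rng(2)
        X = random_design(rng)
        y = rng.standard_normal(30)
        fit = ols_fit(X, y)
        ref = sm.OLS(y, X.matrix).fit()
        np.testing.assert_allclose(fit.beta, ref.params, rtol=1e-10)
        np.testing.assert_allclose(fit.se, ref.bse, rtol=1e-10)
        np.testing.assert_allclose(fit.p_param, ref.pvalues, rtol=1e-8)

    def test_exact_fit_zero_residual(self):
        x = np.arange(10.0)
        X = DesignMatrix(["intercept", "x"], np.column_stack([np.ones(10), x]))
        fit = ols_fit(X, 2 * x)
        assert fit.term("x").beta == pytest.approx(2.0)
        assert fit.rss == pytest.approx(0.0, abs=1e-20)

    def test_intercept_only_t_equals_one_sample_t(self):
        rng = np.random.default_rng(3)
        y = rng.standard_normal(15) + 0.4
        X = DesignMatrix(["intercept"], np.ones((15, 1)))
        fit = ols_fit(X, y)
        t, df, p = one_sample_t(y)
        assert fit.term("intercept").t == pytest.approx(t, rel=1e-12)
        assert fit.df == df + 1 - 1  # n - 1 either way

    def test_rank_deficiency_names_collinear_terms(self):
        n = 20
        rng = np.random.default_rng(4)
        a = rng.standard_normal(n)
        X = DesignMatrix(["intercept", "a", "twice_a"],
                         np.column_stack([np.ones(n), a, 2 * a]))
        with pytest.raises(SingularDesignError) as exc:
            ols_fit(X, rng.standard_normal(n))
        assert {"a", "twice_a"} <= set(exc.value.terms)

    def test_dropping_subject_changes_df_by_one(self):
        rng = np.random.default_rng(5)
        X = random_design(rng)
        y = rng.standard_normal(30)
        full = ols_fit(X, y)
        sub = ols_fit(DesignMatrix(X.terms, X.matrix[1:]), y[1:])
        assert full.df - sub.df == 1

    def test_interaction_term_built_as_product(self):
        import pandas as pd
        frame = pd.DataFrame({"g": [0, 0, 1, 1.0], "s": [1, 2, 3, 4.0]})
        X = build_design(frame, ["intercept", "g", "s", "g:s"])
        np.testing.assert_array_equal(X.matrix[:, 3], [0, 0, 3, 4])


class TestClassicalTests:
    @pytest.mark.parametrize("mean,sd,n,expected_t", [
        (0.0086, 0.0172, 22, 2.34),    # rightward FA asymmetry, TD
        (0.0140, 0.0231, 28, 3.22),    # rightward FA asymmetry, ASD
        (-0.0051, 0.0062, 28, -4.34),  # MD asymmetry, ASD
        (-0.0069, 0.0127, 22, -2.55),  # AD asymmetry, TD
        (-0.0059, 0.0105, 28, -2.97),  # AD asymmetry, ASD
    ])
    def test_one_sample_from_printed_summaries(self, mean, sd, n, expected_t):
        t, df, p = one_sample_t_from_summary(mean, sd, n)
        assert t == pytest.approx(expected_t, abs=0.05)
        assert df == n - 1

    def test_one_sample_matches_scipy_on_raw_data(self):
        rng = np.random.default_rng(6)
        x = rng.normal(0.02, 0.017, 22)
        t, df, p = one_sample_t(x)
        ref = stats.ttest_1samp(x, 0.0)
        assert t == pytest.approx(ref.statistic, rel=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-12)

    def test_one_sample_zero_variance_degenerate(self):
        with pytest.raises(DegenerateDataError):
            one_sample_t(np.zeros(10))

    @pytest.mark.parametrize("m1,s1,n1,m2,s2,n2,expected_t", [
        (23.59, 7.7, 22, 70.25, 14.13, 28, -13.93),  # parent questionnaire
        (93.51, 4.03, 22, 46.8, 11.9, 28, 17.60),    # language quotient
        (94.07, 4.01, 22, 55.59, 9.15, 28, 18.36),   # personal-social
        (2.97, 1.31, 22, 3.24, 1.26, 28, -0.73),     # age
    ])
    def test_pooled_t_from_printed_summaries(self, m1, s1, n1, m2, s2, n2,
                                             expected_t):
        t, df, p = two_sample_t_from_summary(m1, s1, n1, m2, s2, n2)
        assert t == pytest.approx(expected_t, abs=0.05)
        assert df == 48

    def test_identical_samples_t_zero(self):
        rng = np.random.default_rng(7)
        x = rng.standard_normal(10)
        t, df, p = two_sample_t_pooled(x, x.copy())
        assert t == pytest.approx(0.0, abs=1e-12)
        assert df == 18


def fisher_enumeration_oracle(table):
    """Two-sided Fisher p by explicit enumeration over fixed margins."""
    (a, b), (c, d) = table
    r1, c1, n = a + b, a + c, a + b + c + d
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    ks = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(ks, n, c1, r1)
    p_obs = stats.hypergeom.pmf(a, n, c1, r1)
    return float(pmf[pmf <= p_obs * (1 + 1e-9)].sum())


class TestFisherExact:
    def test_homogeneous_table_p_one(self):
        assert fisher_exact_2x2([[5, 5], [5, 5]]) == pytest.approx(1.0)

    def test_perfect_separation_matches_enumeration(self):
        t = [[10, 0], [0, 10]]
        assert fisher_exact_2x2(t) == pytest.approx(
            fisher_enumeration_oracle(t), rel=1e-10)

    def test_random_tables_match_enumeration(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            tab = rng.integers(1, 15, size=(2, 2))
            assert fisher_exact_2x2(tab) == pytest.approx(
                fisher_enumeration_oracle(tab), rel=1e-9)

    def test_observed_sex_split_p(self):
        # M/F split 17/5 vs 24/4: exact p well above any alpha
        assert fisher_exact_2x2([[17, 5], [24, 4]]) == pytest.approx(
            fisher_enumeration_oracle([[17, 5], [24, 4]]), rel=1e-10)

    def test_negative_and_zero_margin_rejected(self):
        with pytest.raises(TractStatsError):
            fisher_exact_2x2([[-1, 2], [3, 4]])
        with pytest.raises(TractStatsError):
            fisher_exact_2x2([[0, 0], [3, 4]])


class TestPartialR2:
    def test_no_covariates_equals_squared_pearson(self):
        rng = np.random.default_rng(9)
        x, y = rng.standard_normal((2, 40))
        assert partial_r2(x, y) == pytest.approx(
            np.corrcoef(x, y)[0, 1] ** 2, rel=1e-12)

    def test_matches_first_order_recursion_formula(self):
        rng = np.random.default_rng(10)
        x, y, z = rng.standard_normal((3, 60))
        rxy = np.corrcoef(x, y)[0, 1]
        rxz = np.corrcoef(x, z)[0, 1]
        rzy = np.corrcoef(z, y)[0, 1]
        expected = ((rxy - rxz * rzy)
                    / np.sqrt((1 - rxz**2) * (1 - rzy**2))) ** 2
        assert partial_r2(x, y, z) == pytest.approx(expected, rel=1e-10)

    def test_matches_pingouin(self):
        import pandas as pd
        import pingouin as pg
        rng = np.random.default_rng(11)
        df = pd.DataFrame(rng.standard_normal((50, 4)),
                          columns=["x", "y", "age", "sex"])
        ours = partial_r2(df.x, df.y, df[["age", "sex"]].to_numpy())
        ref = pg.partial_corr(df, x="x", y="y", covar=["age", "sex"])
        assert ours == pytest.approx(float(ref["r"].iloc[0]) ** 2, rel=1e-8)

    def test_exact_covariate_function_degenerate(self):
        rng = np.random.default_rng(12)
        z = rng.standard_normal(30)
        with pytest.raises(DegenerateDataError):
            partial_r2(rng.standard_normal(30), 2 * z + 1, z)


class TestPermutation:
    def test_perm_pvalue_counting(self):
        assert perm_pvalue(10.0, [1, 2, 3, 4]) == pytest.approx(1 / 5)
        assert perm_pvalue(0.0, [1, -2, 3, 4]) == pytest.approx(1.0)
        assert perm_pvalue(2.5, [1, -3, 4, 2]) == pytest.approx(3 / 5)

    @given(obs=st.floats(-50, 50),
           nulls=st.lists(st.floats(-50, 50), min_size=1, max_size=40))
    @settings(deadline=None, max_examples=50)
    def test_perm_pvalue_bounds(self, obs, nulls):
        p = perm_pvalue(obs, nulls)
        assert 1 / (len(nulls) + 1) <= p <= 1.0

    def test_same_seed_reproducible(self):
        rng = np.random.default_rng(13)
        X = random_design(rng)
        y = rng.standard_normal(30)
        cfg = PermutationConfig(n_perm=50, seed=99)
        a = permute_term(X, y, "x1", cfg)
        b = permute_term(X, y, "x1", PermutationConfig(n_perm=50, seed=99))
        np.testing.assert_array_equal(a, b)

    def test_schemes_share_null_support_without_covariates(self):
        # with only an intercept beside the tested term, relabelling the
        # predictor and permuting centred residuals generate the same
        # exhaustive null set of t values
        rng = np.random.default_rng(14)
        n = 5
        x = rng.standard_normal(n)
        y = rng.standard_normal(n)
        X = DesignMatrix(["intercept", "x"],
                         np.column_stack([np.ones(n), x]))
        label_ts, fl_ts = [], []
        ybar = y.mean()
        for pi in itertools.permutations(range(n)):
            pi = list(pi)
            Xp = DesignMatrix(X.terms, np.column_stack([np.ones(n), x[pi]]))
            label_ts.append(ols_fit(Xp, y).term("x").t)
            ystar = ybar + (y - ybar)[pi]
            fl_ts.append(ols_fit(X, ystar).term("x").t)
        np.testing.assert_allclose(sorted(label_ts), sorted(fl_ts),
                                   rtol=1e-9)

    def test_mc_null_converges_to_exhaustive(self):
        # n = 5 exhaustive label-permutation null vs Monte-Carlo draw
        rng = np.random.default_rng(15)
        n = 5
        x = rng.standard_normal(n)
        y = rng.standard_normal(n)
        X = DesignMatrix(["intercept", "x"],
                         np.column_stack([np.ones(n), x]))
        exact = np.array([
            ols_fit(DesignMatrix(X.terms,
                                 np.column_stack([np.ones(n), x[list(pi)]])),
                    y).term("x").t
            for pi in itertools.permutations(range(n))])
        cfg = PermutationConfig(n_perm=4000, seed=0,
                                scheme="label_permutation")
        mc = permute_term(X, y, "x", cfg)
        grid = np.sort(exact)
        F_exact = np.searchsorted(np.sort(exact), grid, "right") / exact.size
        F_mc = np.searchsorted(np.sort(mc), grid + 1e-12, "right") / mc.size
        assert np.abs(F_exact - F_mc).max() < 0.03

    def test_multiresponse_nulls_match_single_response(self):
        rng = np.random.default_rng(16)
        X = random_design(rng, n=20)
        Y = rng.standard_normal((20, 3))
        cfg = PermutationConfig(n_perm=30, seed=5)
        joint = perm_null_ts(X, Y, "x1", cfg)
        single = perm_null_ts(X, Y[:, 1], "x1", cfg)
        np.testing.assert_allclose(joint[:, 1], single[:, 0], rtol=1e-10)

    def test_signflip_t_definition(self):
        rng = np.random.default_rng(17)
        v = rng.standard_normal(12)
        nulls = signflip_null_ts(v, 20, np.random.default_rng(1))
        assert nulls.shape == (20, 1)
        # each null t must be a one-sample t of some sign-flipped sample:
        # bounded by the all-same-sign configuration
        tmax = np.abs(v).mean() / (np.abs(v).std(ddof=1) + 1e-12) * np.sqrt(12)
        assert np.all(np.isfinite(nulls))


class TestMaxStat:
    def test_single_family_reduces_to_perm_pvalue(self):
        rng = np.random.default_rng(18)
        nulls = rng.standard_normal((200, 1))
        obs = 1.3
        assert maxstat_correct([obs], nulls)[0] == pytest.approx(
            perm_pvalue(obs, nulls[:, 0]))

    def test_duplicated_test_same_corrected_p(self):
        rng = np.random.default_rng(19)
        base = rng.standard_normal(100)
        nulls = np.column_stack([base, base])
        p = maxstat_correct([1.1, 1.1], nulls)
        assert p[0] == p[1]

    def test_corrected_never_below_uncorrected(self):
        rng = np.random.default_rng(20)
        nulls = rng.standard_normal((300, 6))
        obs = rng.standard_normal(6) * 2
        corr = maxstat_correct(obs, nulls)
        raw = np.array([perm_pvalue(o, nulls[:, j])
                        for j, o in enumerate(obs)])
        assert np.all(corr >= raw - 1e-12)

    def test_monotone_in_family_size(self):
        rng = np.random.default_rng(21)
        nulls = rng.standard_normal((300, 8))
        obs = np.full(8, 1.7)
        p_small = maxstat_correct(obs[:3], nulls[:, :3])[0]
        p_large = maxstat_correct(obs, nulls)[0]
        assert p_large >= p_small

    def test_shape_mismatch_rejected(self):
        with pytest.raises(TractStatsError):
            maxstat_correct([1.0, 2.0], np.zeros((10, 3)))

    def test_fwe_calibration_on_independent_nulls(self):
        # 8 independent null tests: familywise rejection at 0.05 stays
        # near nominal under max-statistic correction
        rng = np.random.default_rng(22)
        n, B, reps = 20, 199, 300
        fw = 0
        for _ in range(reps):
            data = rng.standard_normal((n, 8))
            t = data.mean(0) / (data.std(0, ddof=1) / np.sqrt(n))
            nulls = signflip_null_ts(data, B, rng)
            fw += np.any(maxstat_correct(t, nulls) < 0.05)
        rate = fw / reps
        assert rate <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / reps)
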