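import numpy as np
import pandas as pd
import pytest
import scipy.stats as st

from dmnage.stats_models import (
    ancova_binary,
    chi_square_2x2,
    compare_independent_correlations,
    fit_interaction_model,
    group_age_correlation,
    heteroscedasticity_check,
    log_transform_refit,
    partial_correlation,
    pooled_t_from_summary,
)


def make_table(rng, n=200, n_sites=3, slope_age=0.0, slope_interaction=0.0,
               noise_sd=1.0, intercept=3.0, hetero=False):
    """Phenotype + outcome table generated straight from the linear model."""
    dx = rng.integers(0, 2, n)  # 0 = MDD, 1 = HC
    age = rng.uniform(18, 65, n)
    sex = rng.integers(0, 2, n)
    edu = rng.normal(12, 4, n)
    fd = rng.uniform(0.01, 0.15, n)
    site = rng.integers(0, n_sites, n)
    sd = noise_sd * (0.2 + (age - 18) / 47.0) if hetero else noise_sd
    y = (intercept + slope_age * age
         + slope_interaction * dx * (age - age.mean())
         + rng.normal(0, sd, n))
    return pd.DataFrame({
        "subject_id": [f"s{i}" for i in range(n)],
        "diagnosis": np.where(dx == 1, "HC", "MDD"),
        "age": age,
        "sex": np.where(sex == 1, "female", "male"),
        "education": edu,
        "site": [f"site{v}" for v in site],
        "mean_fd": fd,
        "y": y,
    })


class TestInteractionModel:
    def test_exact_fit_on_noise_free_outcome(self, rng):
        t = make_table(rng, n=80, n_sites=1, slope_age=2.0, noise_sd=0.0)
        res = fit_interaction_model(t, "y")
        assert res.coef("age") == pytest.approx(2.0, abs=1e-9)
        assert res.coef("diagnosis_x_age") == pytest.approx(0.0, abs=1e-9)
        assert res.coef("intercept") == pytest.approx(3.0, abs=1e-8)
        assert abs(res.residuals).max() < 1e-9

    def test_parameter_recovery_within_ci(self, rng):
        t = make_table(rng, n=500, slope_age=-0.5, slope_interaction=0.3, noise_sd=1.0)
        res = fit_interaction_model(t, "y")
        for term, truth in (("age", -0.5), ("diagnosis_x_age", 0.3)):
            j = res.terms.index(term)
            se = abs(res.b[j] / res.t[j])
            assert abs(res.b[j] - truth) < 1.96 * se

    def test_matches_normal_equations_oracle(self, rng):
        t = make_table(rng, n=30, n_sites=2, slope_age=0.1, noise_sd=0.5)
        res = fit_interaction_model(t, "y")
        # rebuild the design independently and solve X'Xb = X'y
        dx = (t["diagnosis"] == "HC").to_numpy(float)
        age = t["age"].to_numpy()
        x = np.column_stack([
            np.ones(len(t)), dx, age, dx * (age - age.mean()),
            (t["sex"] == "female").to_numpy(float),
            t["education"].to_numpy(),
            (t["site"] == "site1").to_numpy(float),
            t["mean_fd"].to_numpy(),
        ])
        b = np.linalg.solve(x.T @ x, x.T @ t["y"].to_numpy())
        np.testing.assert_allclose(res.b, b, atol=1e-10)

    def test_interaction_t_invariant_to_age_centering(self, rng):
        t = make_table(rng, n=120, slope_age=0.2, slope_interaction=0.1)
        res = fit_interaction_model(t, "y")
        # uncentered product, mains present: same interaction t and p
        import statsmodels.api as sm
        dx = (t["diagnosis"] == "HC").to_numpy(float)
        age = t["age"].to_numpy()
        x = np.column_stack([
            np.ones(len(t)), dx, age, dx * age,
            (t["sex"] == "female").to_numpy(float), t["education"].to_numpy(),
            (t["site"] == "site1").to_numpy(float),
            (t["site"] == "site2").to_numpy(float),
            t["mean_fd"].to_numpy(),
        ])
        fit = sm.OLS(t["y"].to_numpy(), x).fit()
        assert res.tstat("diagnosis_x_age") == pytest.approx(fit.tvalues[3], abs=1e-8)
        assert res.pvalue("diagnosis_x_age") == pytest.approx(fit.pvalues[3], abs=1e-10)

    def test_beta_std_invariant_to_predictor_rescaling(self, rng):
        t = make_table(rng, n=150, slope_age=0.3)
        res0 = fit_interaction_model(t, "y")
        t2 = t.copy()
        t2["education"] = t2["education"] * 100.0
        res1 = fit_interaction_model(t2, "y")
        assert res1.beta("education") == pytest.approx(res0.beta("education"), abs=1e-10)

    def test_residuals_sum_to_zero(self, rng):
        t = make_table(rng, n=100, slope_age=0.2, noise_sd=2.0)
        res = fit_interaction_model(t, "y")
        assert res.residuals.sum() == pytest.approx(0.0, abs=1e-7)

    def test_rank_deficiency_names_columns(self, rng):
        t = make_table(rng, n=60, n_sites=2)
        t["education"] = 5.0  # constant column, collinear with intercept
        with pytest.raises(ValueError, match="collinear"):
            fit_interaction_model(t, "y")

    def test_too_few_rows_rejected(self, rng):
        t = make_table(rng, n=6, n_sites=1)  # 7 model terms for one site
        with pytest.raises(ValueError, match="too small"):
            fit_interaction_model(t, "y")


class TestGroupAgeCorrelation:
    def test_outcome_equal_to_age_gives_one(self, rng):
        t = make_table(rng, n=50)
        t["y"] = t["age"]
        assert group_age_correlation(t, "y", "MDD") == pytest.approx(1.0)

    def test_independent_outcome_is_uncorrelated(self, rng):
        t = make_table(rng, n=4000, slope_age=0.0, noise_sd=1.0)
        assert abs(group_age_correlation(t, "y", "HC")) < 0.08

    def test_negated_age_with_small_noise(self, rng):
        t = make_table(rng, n=100)
        t["y"] = -t["age"] + rng.normal(0, 0.1, len(t))
        assert group_age_correlation(t, "y", "MDD") < -0.99


class TestCompareCorrelations:
    def test_identical_inputs_give_zero(self):
        c = compare_independent_correlations(0.4, 100, 0.4, 100)
        assert c.z == pytest.approx(0.0)
        assert c.p == pytest.approx(1.0)

    def test_antisymmetric_in_group_order(self):
        a = compare_independent_correlations(-0.31, 971, -0.216, 902)
        b = compare_independent_correlations(-0.216, 902, -0.31, 971)
        assert a.z == pytest.approx(-b.z, abs=1e-12)
        assert a.p == pytest.approx(b.p, abs=1e-12)

    def test_rejects_degenerate_inputs(self):
        with pytest.raises(ValueError):
            compare_independent_correlations(1.0, 100, 0.2, 100)
        with pytest.raises(ValueError):
            compare_independent_correlations(0.5, 3, 0.2, 100)


class TestHeteroscedasticity:
    def test_homoscedastic_model_near_zero_rho(self, rng):
        t = make_table(rng, n=1000, slope_age=0.2, noise_sd=1.0)
        res = fit_interaction_model(t, "y")
        check = heteroscedasticity_check(res, t["age"].to_numpy())
        assert abs(check.rho) < 0.08

    def test_age_proportional_noise_detected(self, rng):
        t = make_table(rng, n=1000, slope_age=0.2, noise_sd=1.0, hetero=True)
        res = fit_interaction_model(t, "y")
        check = heteroscedasticity_check(res, t["age"].to_numpy())
        assert check.rho > 0.3
        assert check.p < 1e-6

    def test_constant_moderator_rejected(self, rng):
        t = make_table(rng, n=50)
        res = fit_interaction_model(t, "y")
        with pytest.raises(ValueError, match="distinct"):
            heteroscedasticity_check(res, np.full(len(t), 5.0))


class TestLogRefit:
    def test_exact_inverse_on_exponential_outcome(self, rng):
        t = make_table(rng, n=80, n_sites=1, slope_age=0.02, noise_sd=0.0)
        t["y"] = np.exp(t["y"])
        res = log_transform_refit(t, "y")
        assert res.log_transformed
        assert res.coef("age") == pytest.approx(0.02, abs=1e-9)
        assert res.coef("intercept") == pytest.approx(3.0, abs=1e-7)

    def test_preserves_t_signs_for_monotone_outcome(self, rng):
        t = make_table(rng, n=400, slope_age=0.03, slope_interaction=0.02, noise_sd=0.2)
        t["y"] = np.exp(t["y"])
        raw = fit_interaction_model(t, "y")
        logf = log_transform_refit(t, "y")
        for term in ("age", "diagnosis_x_age"):
            assert np.sign(raw.tstat(term)) == np.sign(logf.tstat(term))

    def test_nonpositive_outcome_rejected(self, rng):
        t = make_table(rng, n=50)
        t.loc[t.index[0], "y"] = 0.0
        t["y"] = t["y"].clip(lower=0.0)
        with pytest.raises(ValueError, match="undefined"):
            log_transform_refit(t, "y")


class TestPartialCorrelation:
    def test_empty_covariates_equal_plain_pearson(self, rng):
        x = rng.standard_normal(60)
        y = 0.5 * x + rng.standard_normal(60)
        r, p = partial_correlation(x, y, None)
        ref = st.pearsonr(x, y)
        assert r == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_outcome_dominated_by_covariates_gives_near_zero(self, rng):
        # y is a linear function of the covariates up to tiny independent
        # noise; residualizing leaves only that noise, so the partial r is
        # a null correlation at n = 2000
        n = 2000
        c = rng.standard_normal((n, 3))
        x = rng.standard_normal(n) + c[:, 0]
        y = c @ np.array([1.0, -2.0, 0.5]) + 4.0 + 1e-3 * rng.standard_normal(n)
        r_plain = np.corrcoef(x, y)[0, 1]
        r, _ = partial_correlation(x, y, c)
        assert abs(r_plain) > 0.2  # clearly related before adjustment
        assert abs(r) < 0.08

    def test_matches_inverse_correlation_matrix_oracle(self, rng):
        data = rng.standard_normal((50, 4)) @ rng.standard_normal((4, 4))
        x, y, cov = data[:, 0], data[:, 1], data[:, 2:]
        r, _ = partial_correlation(x, y, cov)
        # oracle: precision matrix of [x, y, covs]
        prec = np.linalg.inv(np.corrcoef(np.column_stack([x, y, cov]), rowvar=False))
        oracle = -prec[0, 1] / np.sqrt(prec[0, 0] * prec[1, 1])
        assert r == pytest.approx(oracle, abs=1e-10)

    def test_agrees_with_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        df = pd.DataFrame(rng.standard_normal((60, 4)), columns=["x", "y", "c1", "c2"])
        r, p = partial_correlation(df["x"], df["y"], df[["c1", "c2"]].to_numpy())
        ref = pg.partial_corr(df, x="x", y="y", covar=["c1", "c2"])
        assert r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
        assert p == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-10)

    def test_rank_deficient_covariates_rejected(self, rng):
        x, y = rng.standard_normal(30), rng.standard_normal(30)
        c = np.ones((30, 2))
        with pytest.raises(ValueError, match="rank"):
            partial_correlation(x, y, c)


class TestAncova:
    def test_null_factor_gives_small_f(self, rng):
        t = make_table(rng, n=400, noise_sd=1.0)
        t["episodicity"] = np.where(rng.random(len(t)) < 0.5, "first", "recurrent")
        f, p = ancova_binary(t, "y", "episodicity", ["age", "sex", "education", "site", "mean_fd"])
        assert p > 0.001
        assert f < 12.0

    def test_shifted_level_strongly_detected(self, rng):
        t = make_table(rng, n=200, noise_sd=0.01)
        t["episodicity"] = np.where(np.arange(len(t)) % 2 == 0, "first", "recurrent")
        t.loc[t["episodicity"] == "recurrent", "y"] += 1.0
        f, p = ancova_binary(t, "y", "episodicity", ["age", "sex", "education", "site", "mean_fd"])
        assert f > 1e4
        assert p < 1e-6

    def test_f_is_square_of_factor_t(self, rng):
        import statsmodels.api as sm
        t = make_table(rng, n=120, noise_sd=1.0)
        t["episodicity"] = np.where(rng.random(len(t)) < 0.4, "first", "recurrent")
        f, p = ancova_binary(t, "y", "episodicity", ["age"])
        x = np.column_stack([
            np.ones(len(t)),
            (t["episodicity"] == "recurrent").to_numpy(float),
            t["age"].to_numpy(),
        ])
        fit = sm.OLS(t["y"].to_numpy(), x).fit()
        assert f == pytest.approx(fit.tvalues[1] ** 2, abs=1e-8)
        assert p == pytest.approx(fit.pvalues[1], abs=1e-12)

    def test_single_level_rejected(self, rng):
        t = make_table(rng, n=50)
        t["episodicity"] = "first"
        with pytest.raises(ValueError, match="2 levels"):
            ancova_binary(t, "y", "episodicity", ["age"])


class TestSummaryTests:
    def test_equal_means_give_zero_t(self):
        t, df, p = pooled_t_from_summary(5.0, 1.0, 50, 5.0, 2.0, 60)
        assert t == pytest.approx(0.0)
        assert df == 108
        assert p == pytest.approx(1.0)

    def test_matches_raw_data_t_on_constructed_dataset(self):
        # a dataset with exactly the requested mean and SD per group
        def group(m, sd, n):
            base = np.linspace(-1, 1, n)
            base = (base - base.mean()) / base.std(ddof=1)
            return m + sd * base

        g1, g2 = group(3.0, 1.5, 41), group(2.2, 2.0, 57)
        t_raw, p_raw = st.ttest_ind(g1, g2, equal_var=True)
        t, df, p = pooled_t_from_summary(3.0, 1.5, 41, 2.2, 2.0, 57)
        assert t == pytest.approx(t_raw, abs=1e-10)
        assert p == pytest.approx(p_raw, abs=1e-10)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            pooled_t_from_summary(1.0, 0.0, 10, 1.0, 0.0, 10)

    def test_chi_square_closed_form(self):
        chi2, _ = chi_square_2x2(10, 20, 20, 10)
        assert chi2 == pytest.approx(60 * (10 * 10 - 20 * 20) ** 2 / 30**4, abs=1e-10)

    def test_proportional_table_gives_zero(self):
        chi2, p = chi_square_2x2(10, 20, 30, 60)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            chi_square_2x2(0, 0, 5, 5)


def test_interaction_type1_error_near_nominal():
    """Null interaction rejected at ~5%: 500 phenotype-level replicates."""
    from dmnage.pipeline import interaction_type1_error

    rate = interaction_type1_error(n_replicates=500, n_per_group=200, seed=123)
    assert 0.03 <= rate <= 0.07
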