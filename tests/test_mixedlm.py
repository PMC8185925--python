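import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from rametab import MixedModelSpec, fit_lmm, fit_logistic_mm, lmm_scan


def gaussian_fixture():
    """Two-visit cohort with a true random intercept (fixed draw)."""
    rng = np.random.default_rng(42)
    n_pat, n_vis = 30, 2
    pat = np.repeat(np.arange(n_pat), n_vis)
    x = rng.normal(1, 0.5, n_pat * n_vis)
    age = np.repeat(rng.normal(60, 10, n_pat), n_vis)
    u = rng.normal(0, 0.8, n_pat)
    y = 3 + 0.5 * x + 0.01 * age + u[pat] + rng.normal(0, 0.5, n_pat * n_vis)
    return pd.DataFrame(dict(y=y, x=x, age=age, patient=pat))


def binomial_fixture():
    rng = np.random.default_rng(2024)
    n_pat = 40
    pat = np.repeat(np.arange(n_pat), 2)
    x = rng.lognormal(0, 0.5, 80)
    age = np.repeat(rng.normal(60, 10, n_pat), 2)
    u = rng.normal(0, 1.0, n_pat)
    eta = -1.0 + 0.8 * x + 0.02 * (age - 60) + u[pat]
    y = (rng.random(80) < expit(eta)).astype(float)
    return pd.DataFrame(dict(y=y, x=x, age=age, patient=pat))


# REML fit of gaussian_fixture() by lmerTest 3.1-3 / lme4 1.1-37
# (y ~ x + age + (1|patient), Satterthwaite df), frozen as the oracle.
LMERTEST_ORACLE = {
    "(Intercept)": (2.7767095425, 1.3614381874, 28.0629613, 0.0509115232),
    "x": (0.2614844402, 0.2061521124, 39.2770465, 0.2121199095),
    "age": (0.0138718922, 0.0229002519, 27.9335480, 0.5495697091),
}
LMERTEST_VC = (0.620035719, 0.188446164)

# Laplace fit of binomial_fixture() by lme4::glmer (nAGQ=1), frozen.
GLMER_ORACLE = {
    "(Intercept)": (-1.9914088977, 1.7577428772, 0.257241438),
    "x": (0.6314206933, 0.4879733599, 0.195677337),
    "age": (0.0186583816, 0.0275423629, 0.498124909),
}
GLMER_VC = 0.413415799


class TestLinearMixedModel:
    def test_matches_lmertest_reference_fit(self):
        fit = fit_lmm(gaussian_fixture(),
                      MixedModelSpec("y", ["x", "age"], "patient"))
        for term, (est, se, df, p) in LMERTEST_ORACLE.items():
            assert fit.coefficients[term] == pytest.approx(est, abs=5e-6)
            assert fit.standard_errors[term] == pytest.approx(se, rel=1e-4)
            assert fit.dfs[term] == pytest.approx(df, rel=1e-3)
            assert fit.p_values[term] == pytest.approx(p, rel=1e-3)
        su2, se2 = fit.variance_components
        assert su2 == pytest.approx(LMERTEST_VC[0], rel=1e-4)
        assert se2 == pytest.approx(LMERTEST_VC[1], rel=1e-4)

    def test_matches_statsmodels_variance_components(self):
        import statsmodels.formula.api as smf
        data = gaussian_fixture()
        fit = fit_lmm(data, MixedModelSpec("y", ["x", "age"], "patient"))
        m = smf.mixedlm("y ~ x + age", data, groups=data["patient"]
                        ).fit(reml=True)
        assert fit.coefficients["x"] == pytest.approx(m.params["x"], abs=1e-4)
        assert fit.variance_components[0] == pytest.approx(
            float(m.cov_re.iloc[0, 0]), rel=1e-3)
        assert fit.variance_components[1] == pytest.approx(
            float(m.scale), rel=1e-3)

    @pytest.mark.parametrize("seed", range(5))
    def test_singleton_groups_reduce_to_ols(self, seed):
        """With one row per group the REML optimum sits at the boundary and
        estimates equal ordinary least squares with n - p df."""
        rng = np.random.default_rng(seed)
        n = 25
        data = pd.DataFrame({
            "y": rng.normal(0, 1, n),
            "x": rng.normal(0, 1, n),
            "patient": np.arange(n)})
        fit = fit_lmm(data, MixedModelSpec("y", ["x"], "patient"))
        X = np.column_stack([np.ones(n), data["x"]])
        beta = np.linalg.lstsq(X, data["y"], rcond=None)[0]
        assert fit.coefficients["(Intercept)"] == pytest.approx(beta[0],
                                                                abs=1e-6)
        assert fit.coefficients["x"] == pytest.approx(beta[1], abs=1e-6)
        assert fit.dfs["x"] == pytest.approx(n - 2, abs=1e-6)
        assert fit.fallback == "ols_boundary"

    def test_paired_design_satterthwaite_df_is_n_patients_minus_1(self):
        """For the balanced paired design (visit effect, strong patient
        intercept) the Satterthwaite df equals the classical paired-test
        df, n_patients - 1."""
        rng = np.random.default_rng(7)
        n_pat = 20
        pat = np.repeat(np.arange(n_pat), 2)
        visit = np.tile([0.0, 1.0], n_pat)
        u = rng.normal(0, 2.0, n_pat)
        y = 1.0 + 0.5 * visit + u[pat] + rng.normal(0, 0.3, 2 * n_pat)
        data = pd.DataFrame(dict(y=y, visit=visit, patient=pat))
        fit = fit_lmm(data, MixedModelSpec("y", ["visit"], "patient"))
        assert fit.dfs["visit"] == pytest.approx(n_pat - 1, rel=0.02)
        # and the p-value matches the paired t-test
        from scipy.stats import ttest_rel
        t = ttest_rel(y[visit == 1], y[visit == 0])
        assert fit.p_values["visit"] == pytest.approx(t.pvalue, rel=0.02)

    def test_variance_component_recovery_large_n(self):
        rng = np.random.default_rng(123)
        n_pat = 400
        pat = np.repeat(np.arange(n_pat), 2)
        u = rng.normal(0, 0.9, n_pat)
        x = rng.normal(0, 1, 2 * n_pat)
        y = 1 + 0.4 * x + u[pat] + rng.normal(0, 0.6, 2 * n_pat)
        fit = fit_lmm(pd.DataFrame(dict(y=y, x=x, patient=pat)),
                      MixedModelSpec("y", ["x"], "patient"))
        su2, se2 = fit.variance_components
        assert su2 == pytest.approx(0.81, abs=0.15)
        assert se2 == pytest.approx(0.36, abs=0.08)

    def test_constant_response_rejected(self):
        data = pd.DataFrame({"y": [1.0] * 6, "x": [1, 2, 3, 4, 5, 6.0],
                             "patient": [0, 0, 1, 1, 2, 2]})
        with pytest.raises(ValueError, match="constant"):
            fit_lmm(data, MixedModelSpec("y", ["x"], "patient"))

    def test_singular_design_names_collinear_terms(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 12)
        data = pd.DataFrame({"y": rng.normal(0, 1, 12), "x": x,
                             "x2": 2 * x,
                             "patient": np.repeat(np.arange(6), 2)})
        with pytest.raises(ValueError, match="x2"):
            fit_lmm(data, MixedModelSpec("y", ["x", "x2"], "patient"))

    def test_incumbent_objective_is_monotone_over_iterations(self):
        fit = fit_lmm(gaussian_fixture(),
                      MixedModelSpec("y", ["x", "age"], "patient"))
        trace = np.asarray(fit.trace)
        assert (np.diff(trace) >= -1e-12).all()


class TestLogisticMixedModel:
    def test_matches_glmer_reference_fit(self):
        fit = fit_logistic_mm(binomial_fixture(),
                              MixedModelSpec("y", ["x", "age"], "patient",
                                             family="binomial"))
        for term, (est, se, p) in GLMER_ORACLE.items():
            assert fit.coefficients[term] == pytest.approx(est, abs=2e-3)
            assert fit.standard_errors[term] == pytest.approx(se, rel=5e-3)
            assert fit.p_values[term] == pytest.approx(p, rel=2e-2)
        assert fit.variance_components[0] == pytest.approx(GLMER_VC, abs=5e-3)

    @pytest.mark.parametrize("seed", range(3))
    def test_singleton_groups_reduce_to_plain_logistic(self, seed):
        rng = np.random.default_rng(seed)
        n = 150
        x = rng.normal(0, 1, n)
        y = (rng.random(n) < expit(-0.2 + 0.7 * x)).astype(float)
        data = pd.DataFrame(dict(y=y, x=x, patient=np.arange(n)))
        fit = fit_logistic_mm(data, MixedModelSpec("y", ["x"], "patient",
                                                   family="binomial"))
        import statsmodels.api as sm
        glm = sm.GLM(y, sm.add_constant(x),
                     family=sm.families.Binomial()).fit()
        assert fit.coefficients["(Intercept)"] == pytest.approx(
            glm.params[0], abs=1e-4)
        assert fit.coefficients["x"] == pytest.approx(glm.params[1],
                                                      abs=1e-4)
        assert fit.standard_errors["x"] == pytest.approx(glm.bse[1],
                                                         rel=1e-3)

    def test_perfect_separation_is_flagged_not_silent(self):
        x = np.r_[np.zeros(10), np.ones(10)]
        y = x.copy()
        data = pd.DataFrame(dict(y=y, x=x,
                                 patient=np.tile(np.arange(10), 2)))
        fit = fit_logistic_mm(data, MixedModelSpec("y", ["x"], "patient",
                                                   family="binomial"))
        assert not fit.converged
        assert fit.fallback == "separation"

    def test_single_class_response_rejected(self):
        data = pd.DataFrame({"y": [1.0] * 8, "x": np.arange(8.0),
                             "patient": np.repeat(np.arange(4), 2)})
        with pytest.raises(ValueError, match="single class"):
            fit_logistic_mm(data, MixedModelSpec("y", ["x"], "patient",
                                                 family="binomial"))


class TestBatchScan:
    def test_batch_agrees_with_single_fits(self):
        rng = np.random.default_rng(9)
        n, M = 36, 7
        pat = np.repeat(np.arange(12), 3)
        age = np.repeat(rng.normal(60, 8, 12), 3)
        u = rng.normal(0, 0.7, 12)
        Xcols = rng.lognormal(0, 0.6, (n, M))
        y = 2 + 0.5 * Xcols[:, 0] + u[pat] + rng.normal(0, 0.4, n)
        Xb = np.empty((M, n, 3))
        Xb[:, :, 0] = 1.0
        Xb[:, :, 1] = Xcols.T
        Xb[:, :, 2] = age
        res = lmm_scan(y, Xb, pat)
        for j in range(M):
            data = pd.DataFrame(dict(y=y, x=Xcols[:, j], age=age,
                                     patient=pat))
            fit = fit_lmm(data, MixedModelSpec("y", ["x", "age"], "patient"))
            assert res.beta[j, 1] == pytest.approx(fit.coefficients["x"],
                                                   abs=1e-8)
            assert res.p_value[j, 1] == pytest.approx(fit.p_values["x"],
                                                      rel=1e-6)

    def test_shape_validation(self):
        with pytest.raises(ValueError):
            lmm_scan(np.zeros((2, 10)), np.zeros((3, 10, 2)),
                     np.repeat(np.arange(5), 2))
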