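"""Cox engine against a brute-force partial-likelihood oracle and closed forms."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.optimize import minimize_scalar

from befish.cox import (Covariate, ModelSpec, compare_nested, fit_cox,
                        spline_basis)

from conftest import survival_frame


def oracle_efron_loglik(x, time, event, beta):
    """Naive loop implementation of the Efron partial log-likelihood (1-D)."""
    eta = beta * np.asarray(x, float)
    theta = np.exp(eta)
    ll = 0.0
    for t in sorted(set(np.asarray(time)[np.asarray(event, bool)])):
        d_idx = [i for i in range(len(time)) if event[i] and time[i] == t]
        r_idx = [i for i in range(len(time)) if time[i] >= t]
        d = len(d_idx)
        for l, i in enumerate(d_idx):
            ll += eta[i]
            ll -= np.log(sum(theta[j] for j in r_idx)
                         - (l / d) * sum(theta[j] for j in d_idx))
    return ll


TOYS = [
    # (x, time, event) including ties in event times
    ([0, 1, 0, 1, 2, 1], [3, 5, 7, 2, 8, 8], [1, 1, 0, 1, 1, 0]),
    ([1.5, -0.5, 0.0, 2.0, 1.0, -1.0], [4, 4, 6, 1, 9, 9], [1, 1, 1, 1, 1, 1]),
    ([1, 0, 2, 1, 0, 1], [1, 2, 3, 4, 5, 6], [1, 1, 0, 1, 1, 1]),
]


class TestFitAgainstOracle:
    @pytest.mark.parametrize("x,time,event", TOYS)
    def test_newton_matches_grid_maximizer(self, x, time, event):
        feat = pd.DataFrame({"x": x}, index=[f"P{i}" for i in range(len(x))])
        out = pd.DataFrame({"followup_months": time, "progressed": event},
                           index=feat.index)
        fit = fit_cox(feat, out, ModelSpec("toy", (Covariate("x"),)))
        res = minimize_scalar(
            lambda b: -oracle_efron_loglik(x, time, event, b),
            bounds=(-10, 10), method="bounded",
            options={"xatol": 1e-10})
        assert fit.beta.iloc[0] == pytest.approx(res.x, abs=1e-4)
        assert fit.log_likelihood == pytest.approx(-res.fun, abs=1e-6)

    def test_hr_recovery_on_synthetic_survival(self):
        rng = np.random.default_rng(42)
        n = 2000
        x = rng.integers(0, 2, size=n).astype(float)
        t = rng.exponential(1.0 / (0.05 * 2.0 ** x))
        c = np.full(n, 30.0)
        feat = pd.DataFrame({"x": x}, index=range(n))
        out = pd.DataFrame({"followup_months": np.minimum(t, c),
                            "progressed": t <= c}, index=range(n))
        fit = fit_cox(feat, out, ModelSpec("hr2", (Covariate("x"),)))
        assert 1.8 <= fit.hazard_ratios.iloc[0] <= 2.2


class TestFitProperties:
    def test_constant_covariate_collapses_to_null(self):
        feat = pd.DataFrame({"x": [1.0] * 6}, index=range(6))
        out = pd.DataFrame({"followup_months": [3, 5, 7, 2, 8, 8],
                            "progressed": [1, 1, 0, 1, 1, 0]}, index=range(6))
        fit = fit_cox(feat, out, ModelSpec("const", (Covariate("x"),)))
        assert len(fit.beta) == 0
        assert fit.lr_p == 1.0
        assert fit.aic == pytest.approx(-2 * fit.null_log_likelihood)

    def test_zero_events_error(self):
        feat = pd.DataFrame({"x": [0.0, 1.0]}, index=range(2))
        out = pd.DataFrame({"followup_months": [5, 6],
                            "progressed": [False, False]}, index=range(2))
        with pytest.raises(ValueError, match="no events"):
            fit_cox(feat, out, ModelSpec("none", (Covariate("x"),)))

    def test_ci_is_exp_beta_pm_196_se(self):
        df = survival_frame(300, np.random.default_rng(1), beta=0.7)
        fit = fit_cox(df[["x"]], df, ModelSpec("m", (Covariate("x"),)))
        b, se = fit.beta.iloc[0], fit.se.iloc[0]
        assert fit.ci_lower.iloc[0] == pytest.approx(np.exp(b - 1.96 * se))
        assert fit.ci_upper.iloc[0] == pytest.approx(np.exp(b + 1.96 * se))

    def test_row_order_invariance(self):
        df = survival_frame(120, np.random.default_rng(2), beta=0.5)
        spec = ModelSpec("m", (Covariate("x"),))
        a = fit_cox(df[["x"]], df, spec)
        shuffled = df.sample(frac=1, random_state=9)
        b = fit_cox(shuffled[["x"]], shuffled, spec)
        assert a.beta.iloc[0] == pytest.approx(b.beta.iloc[0], abs=1e-8)
        assert a.log_likelihood == pytest.approx(b.log_likelihood, abs=1e-8)

    def test_affine_rescaling_rescales_beta(self):
        df = survival_frame(150, np.random.default_rng(3), beta=0.6)
        spec = ModelSpec("m", (Covariate("x"),))
        a = fit_cox(df[["x"]], df, spec)
        df2 = df.copy()
        df2["x"] = 10.0 * df2["x"] + 5.0
        b = fit_cox(df2[["x"]], df2, spec)
        assert b.beta.iloc[0] == pytest.approx(a.beta.iloc[0] / 10.0, rel=1e-5)
        assert b.log_likelihood == pytest.approx(a.log_likelihood, abs=1e-6)

    def test_max_covariates_cap_refused(self):
        covs = tuple(Covariate(f"x{i}") for i in range(4))
        with pytest.raises(ValueError, match="overfitting"):
            ModelSpec("big", covs)

    def test_overfitting_guard_warns(self):
        rng = np.random.default_rng(4)
        df = survival_frame(60, rng, beta=0.0)
        df["y"] = rng.normal(size=60)
        df["progressed"] = False
        df.iloc[:5, df.columns.get_loc("progressed")] = True
        with pytest.warns(UserWarning, match="1-per-10"):
            fit_cox(df[["x", "y"]], df,
                    ModelSpec("m", (Covariate("x"), Covariate("y"))))


class TestSplineBasis:
    def test_df1_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            spline_basis(np.arange(10.0), df=1)

    def test_too_few_distinct_values_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            spline_basis(np.array([1.0, 1.0, 2.0, 2.0]), df=3)

    def test_deterministic_and_df_columns(self):
        x = np.random.default_rng(0).normal(size=40)
        a = spline_basis(x, df=3)
        b = spline_basis(x, df=3)
        assert a.shape == (40, 3)
        np.testing.assert_allclose(a.values, b.values)

    def test_spline_fit_transform_consistency(self):
        from befish.cox import NaturalSplineBasis
        x = np.linspace(0, 10, 50)
        basis = NaturalSplineBasis(3)
        fitted = basis.fit(x)
        again = basis.transform(x)
        np.testing.assert_allclose(fitted.values, again.values, atol=1e-12)


class TestCompareNested:
    def _fit(self, df, spline):
        cov = Covariate("x", spline=spline, spline_df=3)
        return fit_cox(df[["x"]], df, ModelSpec("m", (cov,)))

    def test_identical_models_chi2_zero(self):
        df = survival_frame(100, np.random.default_rng(5), beta=0.4)
        a = self._fit(df, False)
        chi2, dof, p = compare_nested(a, a)
        assert chi2 == 0.0 and p == 1.0

    def test_chi2_quantile_identity(self):
        # df=2, chi2=5.99 sits at the 5% tail of the chi-square distribution
        assert stats.chi2.sf(5.99, 2) == pytest.approx(0.05, abs=1e-3)

    def test_non_nested_error(self):
        df = survival_frame(100, np.random.default_rng(6), beta=0.4)
        df["y"] = np.random.default_rng(7).normal(size=100)
        a = fit_cox(df[["x"]], df, ModelSpec("a", (Covariate("x"),)))
        b = fit_cox(df[["y"]], df, ModelSpec("b", (Covariate("y"),)))
        with pytest.raises(ValueError, match="nested"):
            compare_nested(a, b)

    def test_linear_hazard_rarely_prefers_spline(self):
        rng = np.random.default_rng(8)
        rejections = 0
        reps = 60
        for _ in range(reps):
            df = survival_frame(250, rng, beta=0.8)
            lin = self._fit(df, False)
            spl = self._fit(df, True)
            _, _, p = compare_nested(lin, spl)
            rejections += p <= 0.05
        assert rejections / reps < 0.35  # no systematic spline preference

    def test_ushaped_hazard_prefers_spline(self):
        rng = np.random.default_rng(9)
        wins = 0
        reps = 40
        for _ in range(reps):
            x = rng.uniform(-2, 2, size=300)
            lp = 1.5 * x ** 2
            t = rng.exponential(1.0 / (0.1 * np.exp(lp)))
            c = rng.exponential(8.0, size=300)
            df = pd.DataFrame({"x": x, "followup_months": np.minimum(t, c),
                               "progressed": t <= c}, index=range(300))
            lin = self._fit(df, False)
            spl = self._fit(df, True)
            _, _, p = compare_nested(lin, spl)
            decision_matches = (p <= 0.05) == (
                spl.log_likelihood - lin.log_likelihood >
                0.5 * stats.chi2.ppf(0.95, len(spl.beta) - len(lin.beta)))
            assert decision_matches
            wins += p <= 0.05
        assert wins / reps > 0.8  # strong curvature is detected in most reps

    def test_aic_differs_by_2dk_at_equal_loglik(self):
        df = survival_frame(100, np.random.default_rng(10), beta=0.4)
        lin = self._fit(df, False)
        # AIC identity: same loglik implies AIC difference 2 * dk
        assert lin.aic == pytest.approx(-2 * lin.log_likelihood + 2 * len(lin.beta))
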