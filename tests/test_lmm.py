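import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import multivariate_normal

from panelits.errors import ValidationError
from panelits.lmm import (
    VarianceComponents,
    ar1_corr,
    fit,
    information_criteria,
    marginal_loglik,
    residual_diagnostics,
)


class TestAr1Corr:
    def test_closed_form(self):
        np.testing.assert_allclose(
            ar1_corr(3, 0.5),
            [[1, 0.5, 0.25], [0.5, 1, 0.5], [0.25, 0.5, 1]],
        )

    def test_rho_zero_identity(self):
        np.testing.assert_array_equal(ar1_corr(4, 0.0), np.eye(4))

    def test_gap_convention(self):
        R = ar1_corr(2, 0.5, gaps=[0, 2])
        assert R[0, 1] == pytest.approx(0.25)

    def test_invalid_rho(self):
        with pytest.raises(ValidationError):
            ar1_corr(3, 1.0)

    def test_negative_rho_alternates(self):
        R = ar1_corr(3, -0.5)
        assert R[0, 1] == pytest.approx(-0.5)
        assert R[0, 2] == pytest.approx(0.25)


def _dense_oracle_loglik(beta, vc, X, Z, y, groups, times=None):
    """Independent check: assemble each block's dense covariance
    V = Z G Z' + sigma2 * R(rho) and sum scipy MVN log-densities."""
    groups = np.asarray(groups)
    ll = 0.0
    for g in pd.unique(groups):
        idx = np.flatnonzero(groups == g)
        t = np.arange(len(idx)) if times is None else np.asarray(times)[idx]
        R = ar1_corr(len(idx), vc.rho, gaps=t - t[0])
        V = Z[idx] @ vc.G @ Z[idx].T + vc.sigma2 * R
        ll += multivariate_normal.logpdf(y[idx], mean=X[idx] @ beta, cov=V)
    return ll


def _toy_block_data(seed=0, n_per_block=(4, 3, 5), p=2):
    rng = np.random.default_rng(seed)
    groups = np.concatenate([[i] * n for i, n in enumerate(n_per_block)])
    n = len(groups)
    X = np.column_stack([np.ones(n), rng.standard_normal(n)])[:, :p]
    times = np.concatenate([np.arange(k, dtype=float) for k in n_per_block])
    Z = np.column_stack([np.ones(n), times])
    y = rng.standard_normal(n)
    return X, Z, y, groups, times


class TestMarginalLoglik:
    def test_single_obs_standard_normal(self):
        vc = VarianceComponents(sigma2=1.0, rho=0.0, G=np.zeros((2, 2)))
        ll = marginal_loglik(
            np.array([0.0]),
            vc,
            np.ones((1, 1)),
            np.zeros((1, 2)),
            np.zeros(1),
            np.array(["A"]),
        )
        assert ll == pytest.approx(-0.5 * math.log(2 * math.pi), abs=1e-12)

    @pytest.mark.parametrize("rho", [0.0, 0.5, -0.4, 0.9])
    @pytest.mark.parametrize(
        "G",
        [
            np.zeros((2, 2)),
            np.array([[0.5, 0.1], [0.1, 0.2]]),
            np.array([[1.0, 0.0], [0.0, 0.0]]),
        ],
    )
    def test_matches_dense_oracle(self, rho, G):
        X, Z, y, groups, times = _toy_block_data()
        vc = VarianceComponents(sigma2=0.7, rho=rho, G=G)
        beta = np.array([0.3, -0.2])
        mine = marginal_loglik(beta, vc, X, Z, y, groups, times)
        oracle = _dense_oracle_loglik(beta, vc, X, Z, y, groups, times)
        assert mine == pytest.approx(oracle, abs=1e-10)

    def test_matches_dense_oracle_with_gaps(self):
        X, Z, y, groups, times = _toy_block_data()
        times = times * 2 + np.array([0, 1, 3, 4, 0, 0, 2, 0, 1, 2, 3, 9])[: len(times)]
        # keep times increasing within block
        times = np.concatenate([np.sort(times[groups == g]) for g in [0, 1, 2]])
        vc = VarianceComponents(sigma2=0.5, rho=0.6, G=np.array([[0.3, 0.0], [0.0, 0.01]]))
        beta = np.array([0.1, 0.2])
        mine = marginal_loglik(beta, vc, X, Z, y, groups, times)
        oracle = _dense_oracle_loglik(beta, vc, X, Z, y, groups, times)
        assert mine == pytest.approx(oracle, abs=1e-10)

    def test_sigma2_doubling_identity(self):
        # with zero residuals and no random effects, doubling sigma2 lowers
        # the log-likelihood by n/2 * ln 2
        n = 8
        X = np.ones((n, 1))
        Z = np.zeros((n, 2))
        y = np.zeros(n)
        groups = np.zeros(n)
        ll1 = marginal_loglik(
            np.zeros(1), VarianceComponents(1.0, 0.0, np.zeros((2, 2))), X, Z, y, groups
        )
        ll2 = marginal_loglik(
            np.zeros(1), VarianceComponents(2.0, 0.0, np.zeros((2, 2))), X, Z, y, groups
        )
        assert ll1 - ll2 == pytest.approx(0.5 * n * math.log(2), abs=1e-10)


class TestInformationCriteria:
    def test_closed_form(self):
        aic, bic = information_criteria(0.0, 3, int(round(math.e**2)))
        assert aic == pytest.approx(6.0)
        assert bic == pytest.approx(3 * math.log(round(math.e**2)))

    def test_arithmetic(self):
        aic, bic = information_criteria(-100.0, 10, 100)
        assert aic == pytest.approx(220.0)
        assert bic == pytest.approx(246.0517, abs=1e-3)

    def test_aic_below_bic_iff_n_above_e2(self):
        for n in [5, 7, 8, 20]:
            aic, bic = information_criteria(-5.0, 2, n)
            assert (aic < bic) == (n > math.e**2)


class TestFit:
    def _ols_data(self, seed=1, n_blocks=3, n_per=40):
        rng = np.random.default_rng(seed)
        groups = np.repeat(np.arange(n_blocks), n_per)
        n = len(groups)
        X = np.column_stack([np.ones(n), rng.standard_normal(n), rng.standard_normal(n)])
        times = np.tile(np.arange(n_per, dtype=float), n_blocks)
        Z = np.column_stack([np.ones(n), times])
        beta = np.array([1.0, 0.5, -0.25])
        y = X @ beta + 0.3 * rng.standard_normal(n)
        return X, Z, y, groups, times

    def test_gls_equals_ols_when_variance_structure_off(self):
        X, Z, y, groups, times = self._ols_data()
        res = fit(X, Z, y, groups, times=times, estimate_rho=False, estimate_G=False)
        beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        np.testing.assert_allclose(res.beta.to_numpy(), beta_ols, atol=1e-8)
        # and the ML log-likelihood equals the closed-form OLS one
        n = len(y)
        rss = float(np.sum((y - X @ beta_ols) ** 2))
        s2_ml = rss / n
        ll_ols = -0.5 * n * (math.log(2 * math.pi * s2_ml) + 1.0)
        assert res.loglik == pytest.approx(ll_ols, abs=1e-6)

    def test_profiled_optimality(self):
        X, Z, y, groups, times = self._ols_data()
        res = fit(X, Z, y, groups, times=times, estimate_rho=False, estimate_G=False)
        base = marginal_loglik(res.beta.to_numpy(), res.vc, X, Z, y, groups, times)
        for j in range(X.shape[1]):
            for eps in (1e-4, -1e-4):
                b = res.beta.to_numpy().copy()
                b[j] += eps
                assert marginal_loglik(b, res.vc, X, Z, y, groups, times) <= base + 1e-12

    def test_rank_deficiency_named(self):
        X, Z, y, groups, times = self._ols_data()
        Xdf = pd.DataFrame(X, columns=["intercept", "x1", "x2"])
        Xdf["dup"] = Xdf["x1"]
        with pytest.raises(ValidationError, match="dup"):
            fit(Xdf, Z, y, groups, times=times)

    def test_reml_runs_and_differs_from_ml(self):
        X, Z, y, groups, times = self._ols_data()
        ml = fit(X, Z, y, groups, times=times, estimate_G=False, n_starts=1)
        reml = fit(X, Z, y, groups, times=times, estimate_G=False, method="reml", n_starts=1)
        assert reml.loglik != pytest.approx(ml.loglik)

    def test_variance_recovery_small(self):
        # sigma2/rho recovered on a moderate panel; the full-scale version
        # is exercised by the shared recovery fixture in test_acceptance
        from conftest import small_sim_panel, design_for
        from panelits.design import default_schedule
        from panelits.simulate import make_default_metadata, subset_metadata
        from datetime import date

        meta = subset_metadata(make_default_metadata(), {"low": 2, "middle": 2, "high": 2})
        cfg, panel, truth = small_sim_panel(meta, date_range=("2019-09-01", "2020-06-30"), seed=3)
        dm = design_for(panel, meta, default_schedule(), date(2019, 9, 1))
        y = np.log(panel["index"].to_numpy())
        res = fit(dm.X, dm.Z, y, dm.groups, times=dm.times, n_starts=1)
        assert res.vc.sigma2 == pytest.approx(cfg.sigma2, rel=0.25)
        assert res.vc.rho == pytest.approx(cfg.rho, rel=0.15)


class TestDiagnostics:
    def test_whitening_exact_ar1(self):
        # whitening a pure AR(1) sequence leaves white noise
        rng = np.random.default_rng(0)
        n, rho = 5000, 0.7
        eps = np.empty(n)
        eps[0] = rng.standard_normal()
        for t in range(1, n):
            eps[t] = rho * eps[t - 1] + math.sqrt(1 - rho**2) * rng.standard_normal()
        from panelits.lmm import _lag1_acf, _whiten

        groups = np.zeros(n)
        times = np.arange(n, dtype=float)
        assert abs(_lag1_acf(eps, groups, times) - rho) < 0.05
        w, _ = _whiten(eps[:, None], rho, np.diff(times, prepend=0.0))
        assert abs(_lag1_acf(w[:, 0], groups, times)) < 0.05

    def test_correct_model_residuals_white(self):
        from conftest import small_sim_panel, design_for
        from panelits.design import default_schedule
        from panelits.simulate import make_default_metadata, subset_metadata
        from datetime import date

        meta = subset_metadata(make_default_metadata(), {"low": 2, "middle": 2, "high": 2})
        cfg, panel, truth = small_sim_panel(meta, date_range=("2019-09-01", "2020-06-30"), seed=11)
        dm = design_for(panel, meta, default_schedule(), date(2019, 9, 1))
        y = np.log(panel["index"].to_numpy())
        res = fit(dm.X, dm.Z, y, dm.groups, times=dm.times, n_starts=1)
        diag = residual_diagnostics(res, dm.X, dm.Z, y, dm.groups, dm.times)
        assert abs(diag.lag1_whitened) < 0.05
        assert diag.lag1_raw > 0.3  # raw residuals are clearly autocorrelated

    def test_heteroscedasticity_detected(self):
        rng = np.random.default_rng(5)
        n = 2000
        groups = np.repeat([0, 1], n // 2)
        times = np.tile(np.arange(n // 2, dtype=float), 2)
        x = rng.uniform(0, 1, n)
        X = np.column_stack([np.ones(n), x])
        Z = np.column_stack([np.ones(n), times])
        # noise sd doubles with the covariate
        y = 2.0 + 3.0 * x + (0.5 + 1.0 * x) * rng.standard_normal(n)
        res = fit(X, Z, y, groups, times=times, estimate_rho=False, estimate_G=False)
        diag = residual_diagnostics(res, X, Z, y, groups, times)
        assert diag.variance_slope > 0
        assert diag.variance_slope_z > 3
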