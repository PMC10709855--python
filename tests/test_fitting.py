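"""GAMLSS fitting, information criteria, model selection, cross-validation."""

import numpy as np
import pytest
from dataclasses import replace

from bfgrowth.fitting import crossvalidate, fit_gamlss, select_dfs, select_family_smoother
from bfgrowth.synthetic import CurveTruth, TruthSpec, sample_anthro


def bccg_truth(truth, sigma=0.15, nu=1.0):
    return TruthSpec(
        curves={k: CurveTruth("BCCG", c.mu0, c.mu_rate, sigma, nu, None) for k, c in truth.curves.items()}
    )


@pytest.fixture(scope="module")
def boys_weight_sample(truth):
    rng = np.random.default_rng(2)
    t = rng.integers(0, 183, 1200)
    y = sample_anthro(t, truth, "weight", "male", seed=3)
    return t, y


class TestFitGamlss:
    def test_bccg_constant_parameter_recovery(self, truth):
        # constant mu, sigma, nu: df = (0, 0, 0)
        t = np.random.default_rng(4).integers(0, 183, 3000)
        spec = TruthSpec(
            curves={("weight", "male"): CurveTruth("BCCG", 5.0, 0.0, 0.15, 1.0, None)}
        )
        y = sample_anthro(t, spec, "weight", "male", seed=5)
        m = fit_gamlss(t, y, family="BCCG", smoother="ps", df_spec=(0, 0, 0))
        mu, sigma, nu, tau = m.params_at([90.0])
        assert m.converged
        assert mu[0] == pytest.approx(5.0, rel=0.01)
        assert sigma[0] == pytest.approx(0.15, rel=0.05)
        assert nu[0] == pytest.approx(1.0, abs=0.3)
        assert tau is None

    def test_information_criteria_identities(self, fitted_bcpe):
        m = fitted_bcpe
        assert m.aic == pytest.approx(m.deviance + 2 * m.edf, abs=1e-9)
        assert m.bic == pytest.approx(m.deviance + np.log(m.n) * m.edf, abs=1e-9)
        assert np.isfinite(m.deviance) and m.converged

    def test_poly_with_zero_df_is_na(self, boys_weight_sample):
        t, y = boys_weight_sample
        m = fit_gamlss(t, y, family="BCCG", smoother="poly", df_spec=(0, 1, 0))
        assert not m.converged
        assert np.isnan(m.aic) and np.isnan(m.bic)
        assert "not applicable" in m.reason

    def test_nested_df_never_increases_deviance(self, boys_weight_sample):
        t, y = boys_weight_sample
        m1 = fit_gamlss(t, y, family="BCCG", smoother="ps", df_spec=(0, 1, 0))
        m2 = fit_gamlss(t, y, family="BCCG", smoother="ps", df_spec=(0, 2, 0))
        m3 = fit_gamlss(t, y, family="BCCG", smoother="ps", df_spec=(1, 2, 1))
        assert m2.deviance <= m1.deviance + 0.02
        assert m3.deviance <= m2.deviance + 0.02

    def test_self_consistency_refit_on_fitted_median(self, fitted_bcpe):
        # evaluate the fitted median curve, perturb with tiny noise, refit:
        # the median curve must be recovered almost exactly
        ages = np.repeat(np.arange(0.0, 183.0, 2.0), 8)
        mu, _, _, _ = fitted_bcpe.params_at(ages)
        rng = np.random.default_rng(6)
        y = mu * np.exp(rng.normal(0.0, 1e-3, mu.size))
        m = fit_gamlss(ages, y, family="BCCG", smoother="ps", df_spec=(0, 1, 0))
        mu2, _, _, _ = m.params_at(np.arange(0.0, 183.0))
        mu1, _, _, _ = fitted_bcpe.params_at(np.arange(0.0, 183.0))
        assert np.max(np.abs(mu2 - mu1) / mu1) < 1e-3

    def test_rejects_tiny_samples_and_nonpositive_y(self):
        with pytest.raises(ValueError):
            fit_gamlss(np.arange(10.0), np.ones(10), df_spec=(0, 1, 0))
        y = np.ones(100)
        y[0] = -1.0
        with pytest.raises(ValueError):
            fit_gamlss(np.arange(100.0), y, df_spec=(0, 1, 0))


class TestSelectDfs:
    def test_grid_is_exhaustive_64(self, boys_weight_sample):
        t, y = boys_weight_sample
        best, table = select_dfs(t, y, family="BCCG", smoother="ps")
        assert len(table) == 64
        ok = table[np.isfinite(table.BIC) & table.converged]
        assert ok.BIC.min() == table.set_index(["L_df", "M_df", "S_df"]).loc[best, "BIC"]

    def test_linear_log_median_truth_selects_minimal_model(self, boys_weight_sample):
        t, y = boys_weight_sample
        best, _ = select_dfs(t, y, family="BCCG", smoother="ps")
        assert best == (0, 1, 0)


class TestSelectFamilySmoother:
    def test_poly_column_na_with_zero_df(self, boys_weight_sample):
        t, y = boys_weight_sample
        grid = select_family_smoother(t, y, (0, 1, 0))
        assert grid.aic["poly"].isna().all()
        assert np.isfinite(grid.aic[["ps", "cs"]].to_numpy()).sum() == 6
        assert grid.chosen in grid.models

    def test_poly_fitted_when_all_dfs_positive(self, boys_weight_sample):
        t, y = boys_weight_sample
        grid = select_family_smoother(t, y, (1, 1, 1))
        assert np.isfinite(grid.aic.loc["BCPE", "poly"])

    def test_aic_of_nesting_family_close_on_bccg_data(self, truth):
        # BCPE nests BCCG at tau=2: expected AIC penalty ~ +1, never much below
        diffs = []
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            t = rng.integers(0, 183, 600)
            y = sample_anthro(t, bccg_truth(truth), "weight", "male", seed=200 + seed)
            m_g = fit_gamlss(t, y, family="BCCG", smoother="ps", df_spec=(0, 1, 0))
            m_p = fit_gamlss(t, y, family="BCPE", smoother="ps", df_spec=(0, 1, 0))
            diffs.append(m_p.aic - m_g.aic)
        assert np.mean(diffs) >= -2.0


class TestCrossvalidate:
    def test_same_seed_same_split_and_report(self, truth):
        rng = np.random.default_rng(8)
        t = rng.integers(0, 183, 600)
        y = sample_anthro(t, truth, "weight", "male", seed=9)
        a = crossvalidate(t, y, "BCPE", "ps", (0, 1, 0), seed=4)
        b = crossvalidate(t, y, "BCPE", "ps", (0, 1, 0), seed=4)
        assert a["n_train"] == b["n_train"]
        assert a["holdout_deviance"] == b["holdout_deviance"]
        assert a["coverage_pct"] == b["coverage_pct"]
        assert a["n_train"] + a["n_test"] == 600
        assert 0.65 < a["n_train"] / 600 < 0.75

    def test_requires_minimum_sample(self):
        with pytest.raises(ValueError):
            crossvalidate(np.arange(100.0), np.ones(100) + 1, "BCCG", "ps", (0, 0, 0))
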