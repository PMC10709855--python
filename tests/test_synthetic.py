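"""Synthetic survey generator: truth anchoring, determinism, consistency."""

import numpy as np
import pytest
from scipy.stats import kstest

from bfgrowth import selection
from bfgrowth.io_config import RunConfig
from bfgrowth.synthetic import CurveTruth, TruthSpec, default_truth, generate, sample_anthro


class TestDefaultTruth:
    def test_weekly_anchor_means(self, truth):
        # mid-week ages: week 1 ~ day 3, week 26 ~ day 178
        bw = truth.curves[("weight", "male")]
        assert bw.mu(3) == pytest.approx(3.26, abs=0.1)
        assert bw.mu(178) == pytest.approx(6.92, abs=0.1)
        gh = truth.curves[("height", "female")]
        assert gh.mu(3) == pytest.approx(48.87, abs=0.5)

    def test_median_curves_strictly_increasing(self, truth):
        t = np.arange(0, 183)
        for c in truth.curves.values():
            assert np.all(np.diff(c.mu(t)) > 0)

    def test_tau_defaults_are_fitted_chart_values(self, truth):
        taus = [truth.curves[k].tau for k in (("weight", "male"), ("weight", "female"), ("height", "male"), ("height", "female"))]
        assert taus == pytest.approx([1.660418, 1.448022, 1.188859, 1.114607])

    def test_sigma_on_cv_scale_of_weekly_summaries(self, truth):
        # weekly CVs run ~0.20-0.25 (weight) and ~0.06-0.11 (height)
        assert 0.1 < truth.curves[("weight", "male")].sigma < 0.3
        assert 0.03 < truth.curves[("height", "male")].sigma < 0.12


class TestGenerate:
    def test_deterministic_for_fixed_seed(self, truth):
        a = generate(1000, truth, seed=1)
        b = generate(1000, truth, seed=1)
        assert a.equals(b)

    def test_degenerate_prevalences_keep_all(self, truth):
        t = TruthSpec(
            curves=truth.curves,
            p_ebf=1.0,
            p_severe_illness=0.0,
            p_congested=0.0,
            p_singleton=1.0,
            p_fullterm=1.0,
            p_birth_order_le4=1.0,
            p_nonsmoking=1.0,
            p_missing_weight=0.0,
            p_missing_height=0.0,
        )
        df = generate(500, t, seed=2)
        selected, report = selection.select_children(df, RunConfig())
        assert len(selected) == 500
        assert all(v == 500 for v in report.stage_remaining.values())

    def test_independent_criteria_product_yield(self, truth):
        # P(keep) = 0.5 * 0.9 * 0.8 = 0.36 under independence
        t = TruthSpec(
            curves=truth.curves,
            p_ebf=0.5,
            p_severe_illness=0.1,
            p_congested=0.2,
            p_singleton=1.0,
            p_fullterm=1.0,
            p_birth_order_le4=1.0,
            p_nonsmoking=1.0,
        )
        df = generate(10_000, t, seed=3)
        selected, _ = selection.select_children(df, RunConfig())
        frac = len(selected) / len(df)
        se = np.sqrt(0.36 * 0.64 / 10_000)
        assert abs(frac - 0.36) <= 3 * se

    def test_indicators_rederivable_from_raw_variables(self, small_survey):
        ebf = selection.ebf_status(small_survey)
        ill = selection.severe_illness(small_survey)
        cong = selection.adults_per_room(small_survey) > 2.0
        assert np.array_equal(ebf.to_numpy() == 1.0, small_survey["sim_ebf"].to_numpy())
        assert np.array_equal(ill.to_numpy() == 1.0, small_survey["sim_severe_illness"].to_numpy())
        assert np.array_equal(cong.to_numpy(), small_survey["sim_congested"].to_numpy())

    def test_weekly_mean_weight_tracks_truth(self, truth):
        df = generate(20_000, truth, seed=4)
        bw = truth.curves[("weight", "male")]
        m = (df.sex == "male") & df.weight_kg.notna()
        for wk in (2, 10, 20):
            sel = m & (df.age_days // 7 == wk)
            obs = df.loc[sel, "weight_kg"]
            mid = df.loc[sel, "age_days"].mean()
            se = obs.std() / np.sqrt(len(obs))
            # tau near 2 and nu near 1: mean ~ median regime
            assert abs(obs.mean() - bw.mu(mid)) < 3 * se + 0.05

    def test_invalid_truth_rejected_before_sampling(self, truth):
        bad = TruthSpec(curves=truth.curves, p_ebf=1.5)
        with pytest.raises(ValueError):
            generate(10, bad, seed=0)


class TestSampleAnthro:
    def test_z_scores_standard_normal_when_gaussian_kernel(self, truth):
        t = TruthSpec(
            curves={
                k: CurveTruth(family="BCPE", mu0=c.mu0, mu_rate=c.mu_rate, sigma=c.sigma, nu=1.0, tau=2.0)
                for k, c in truth.curves.items()
            }
        )
        rng = np.random.default_rng(6)
        ages = rng.integers(0, 183, 5000)
        y = sample_anthro(ages, t, "weight", "male", seed=7)
        c = t.curves[("weight", "male")]
        z = (np.power(y / c.mu(ages), 1.0) - 1.0) / c.sigma  # nu = 1
        assert kstest(z, "norm").pvalue > 0.01

    def test_degenerate_scale_pins_draws_to_mu(self, truth):
        c0 = truth.curves[("weight", "male")]
        t = TruthSpec(
            curves={("weight", "male"): CurveTruth("BCPE", c0.mu0, c0.mu_rate, 1e-6, 1.0, 2.0)},
        )
        ages = np.arange(0, 183, 10)
        y = sample_anthro(ages, t, "weight", "male", seed=8)
        assert np.max(np.abs(y - c0.mu(ages)) / c0.mu(ages)) < 1e-3

    def test_fixed_seed_identical(self, truth):
        ages = np.arange(0, 100)
        a = sample_anthro(ages, truth, "height", "female", seed=9)
        b = sample_anthro(ages, truth, "height", "female", seed=9)
        assert np.array_equal(a, b)


class TestTruthYaml:
    def test_roundtrip(self, truth, tmp_path):
        p = tmp_path / "truth.yaml"
        truth.to_yaml(p)
        back = TruthSpec.from_yaml(p)
        assert back.p_ebf == truth.p_ebf
        c0, c1 = truth.curves[("weight", "male")], back.curves[("weight", "male")]
        assert c1.mu0 == pytest.approx(c0.mu0)
        assert c1.tau == pytest.approx(c0.tau)
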