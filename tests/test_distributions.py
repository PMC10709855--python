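"""Box-Cox family math: z-transform, densities, cdf/quantile, sampling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad
from scipy.stats import gennorm, kstest

from bfgrowth import distributions as d

LATTICE = [
    (fam, sigma, nu, tau)
    for fam in ("BCCG", "BCPE", "BCT")
    for sigma in (0.05, 0.2)
    for nu in (-1.0, 0.0, 1.0, 2.0)
    for tau in ((None,) if fam == "BCCG" else (1.0, 1.5, 2.0, 5.0))
]


class TestBoxCoxZ:
    def test_identity_at_mu(self):
        for nu in (-1.0, 0.0, 0.5, 2.0):
            assert d.box_cox_z(5.0, 5.0, 0.2, nu) == pytest.approx(0.0, abs=1e-12)

    def test_simple_arithmetic(self):
        # nu=1: z = (y/mu - 1)/sigma
        assert d.box_cox_z(6.0, 5.0, 0.2, 1.0) == pytest.approx(1.0, abs=1e-12)

    def test_continuity_at_nu_zero(self):
        z_small = d.box_cox_z(6.0, 5.0, 0.2, 1e-6)
        z_zero = d.box_cox_z(6.0, 5.0, 0.2, 0.0)
        assert abs(z_small - z_zero) < 1e-6  # series term nu*L^2/2 ~ 1.7e-8
        assert abs(z_small - z_zero) < 1e-6 * abs(z_zero) + 1e-7

    def test_rejects_nonpositive_y(self):
        with pytest.raises(ValueError):
            d.box_cox_z(0.0, 5.0, 0.2, 1.0)


class TestDensities:
    @pytest.mark.parametrize("fam,sigma,nu,tau", LATTICE)
    def test_normalizes_to_one(self, fam, sigma, nu, tau):
        """Quadrature oracle in u = log y, closed with the cdf tail mass.

        The support maps to the line; the heavy-tailed kernels (BCT with
        small tau at nu = 0) keep non-negligible mass beyond any
        float-representable y, so the far tails are accounted via the
        distribution function -- which simultaneously checks that pdf
        and cdf describe the same normalized distribution.
        """
        p = d.DistributionParams(fam, 5.0, sigma, nu, tau)

        def integrand(u):
            y = np.exp(u)
            if y == 0.0 or not np.isfinite(y):
                return 0.0
            return float(np.exp(d.logpdf(y, p) + u))  # pdf(y) * y, overflow-safe

        c = np.log(5.0)
        r = 200 * sigma
        total = float(d.cdf(np.exp(c - r), p)) + float(1.0 - d.cdf(np.exp(c + r), p))
        for a, b in ((c - r, c - 5 * sigma), (c - 5 * sigma, c + 5 * sigma), (c + 5 * sigma, c + r)):
            v, _ = quad(integrand, a, b, limit=400, epsabs=1e-10, epsrel=1e-10)
            total += v
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_bcpe_tau2_equals_bccg(self):
        y = np.linspace(0.5, 12, 200)
        bcpe = d.family_logpdf(y, 5.0, 0.2, 0.5, 2.0, "BCPE")
        bccg = d.family_logpdf(y, 5.0, 0.2, 0.5, None, "BCCG")
        assert np.max(np.abs(bcpe - bccg)) < 1e-10

    def test_bct_large_df_approaches_bccg(self):
        # central 99% of the distribution (the t -> normal error grows ~ z^4/df)
        p = np.linspace(0.005, 0.995, 100)
        y = d.family_quantile(p, 5.0, 0.2, 0.5, None, "BCCG")
        bct = d.family_logpdf(y, 5.0, 0.2, 0.5, 1e6, "BCT")
        bccg = d.family_logpdf(y, 5.0, 0.2, 0.5, None, "BCCG")
        assert np.max(np.abs(bct - bccg)) < 1e-4

    def test_pe_kernel_matches_scipy_gennorm(self):
        t = np.linspace(-4, 4, 81)
        tau = 1.7
        scale = d._pe_scale_c(tau) * 2 ** (1 / tau)
        assert np.allclose(d._kernel_logpdf(t, "BCPE", tau), gennorm.logpdf(t, tau, scale=scale), atol=1e-12)
        assert np.allclose(d._kernel_cdf(t, "BCPE", tau), gennorm.cdf(t, tau, scale=scale), atol=1e-12)

    def test_logpdf_maximized_near_mu_symmetric_case(self):
        y = np.linspace(3.0, 7.0, 4001)
        ll = d.family_logpdf(y, 5.0, 0.1, 1.0, 2.0, "BCPE")
        assert abs(y[np.argmax(ll)] - 5.0) < 0.05


class TestCdfQuantile:
    @pytest.mark.parametrize("fam,tau", [("BCCG", None), ("BCPE", 1.5), ("BCT", 6.0)])
    def test_quantile_cdf_roundtrip(self, fam, tau):
        rng = np.random.default_rng(0)
        for nu in (-0.5, 0.0, 0.7, 2.0):
            # 100 random y spanning the central 99.8% of each distribution
            # (outside it the cdf saturates in double precision by design)
            u = rng.uniform(0.001, 0.999, 100)
            y = d.family_quantile(u, 5.0, 0.2, nu, tau, fam)
            back = d.family_quantile(d.family_cdf(y, 5.0, 0.2, nu, tau, fam), 5.0, 0.2, nu, tau, fam)
            assert np.max(np.abs(back - y)) < 1e-8

    def test_cdf_at_mu_is_half_for_small_sigma(self):
        # truncation mass is Phi(-1/(sigma|nu|)) ~ Phi(-20): negligible
        assert abs(d.family_cdf(5.0, 5.0, 0.05, 1.0, None, "BCCG") - 0.5) < 1e-6

    def test_cdf_strictly_increasing(self):
        y = np.linspace(0.5, 15.0, 300)
        for fam, tau in (("BCCG", None), ("BCPE", 1.2), ("BCT", 4.0)):
            c = d.family_cdf(y, 5.0, 0.2, 0.5, tau, fam)
            assert np.all(np.diff(c) > 0)

    def test_quantile_rejects_bad_p(self):
        with pytest.raises(ValueError):
            d.family_quantile(0.0, 5.0, 0.2, 1.0, None, "BCCG")
        with pytest.raises(ValueError):
            d.family_quantile(1.5, 5.0, 0.2, 1.0, None, "BCCG")

    @settings(deadline=None, max_examples=50)
    @given(
        p=st.floats(0.01, 0.99),
        nu=st.floats(-1.5, 2.5),
        sigma=st.floats(0.03, 0.3),
    )
    def test_quantile_cdf_inverse_property(self, p, nu, sigma):
        y = d.family_quantile(p, 5.0, sigma, nu, 1.5, "BCPE")
        assert y > 0
        assert d.family_cdf(y, 5.0, sigma, nu, 1.5, "BCPE") == pytest.approx(p, abs=1e-8)


class TestLmsCentile:
    def test_median_is_M(self):
        assert d.lms_centile(0.5, 0.7, 5.0, 0.2) == pytest.approx(5.0, abs=1e-12)

    def test_normal_kernel_arithmetic(self):
        # L=1: y = M(1 + S z_p); z_0.975 = 1.959964
        assert d.lms_centile(0.975, 1.0, 5.0, 0.2) == pytest.approx(5 * (1 + 0.2 * 1.959964), abs=1e-4)

    def test_roundtrip_with_box_cox_z(self):
        for p in (0.03, 0.5, 0.97):
            y = d.lms_centile(p, 0.5, 5.0, 0.2)
            z = d.box_cox_z(y, 5.0, 0.2, 0.5)
            from scipy.special import ndtri

            assert z == pytest.approx(ndtri(p), abs=1e-10)

    def test_undefined_argument_raises(self):
        with pytest.raises(ValueError):
            d.lms_centile(0.001, 3.0, 5.0, 0.5)


class TestSampling:
    def test_seed_reproducible_and_positive(self):
        a = d.family_rvs(500, 5.0, 0.2, 1.0, 1.5, "BCPE", seed=7)
        b = d.family_rvs(500, 5.0, 0.2, 1.0, 1.5, "BCPE", seed=7)
        assert np.array_equal(a, b)
        assert np.all(a > 0)

    def test_empirical_cdf_close_to_analytic(self):
        x = d.family_rvs(10000, 5.0, 0.2, 1.0, 1.5, "BCPE", seed=3)
        ks = kstest(x, lambda v: d.family_cdf(v, 5.0, 0.2, 1.0, 1.5, "BCPE")).statistic
        assert ks < 0.02


class TestParamValidation:
    def test_bccg_rejects_tau(self):
        with pytest.raises(ValueError):
            d.DistributionParams("BCCG", 5.0, 0.2, 1.0, 2.0)

    def test_bcpe_requires_tau(self):
        with pytest.raises(ValueError):
            d.DistributionParams("BCPE", 5.0, 0.2, 1.0, None)

    def test_positive_mu_sigma(self):
        with pytest.raises(ValueError):
            d.DistributionParams("BCCG", -1.0, 0.2, 1.0)
        with pytest.raises(ValueError):
            d.DistributionParams("BCCG", 5.0, 0.0, 1.0)
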