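"""Box-Cox distribution families for growth-reference modelling.

Three families from the GAMLSS class, all defined on y > 0 through the
shifted/scaled Box-Cox transform

    z = ((y/mu)^nu - 1) / (nu * sigma)      (nu != 0)
    z = log(y/mu) / sigma                   (nu == 0)

followed by a symmetric kernel on z:

* ``BCCG`` -- Box-Cox Cole and Green (the LMS method): standard normal
  kernel; parameters (mu, sigma, nu).
* ``BCPE`` -- Box-Cox power exponential: power-exponential kernel with
  kurtosis power tau (tau = 2 recovers BCCG); parameters
  (mu, sigma, nu, tau).
* ``BCT`` -- Box-Cox t: Student-t kernel with tau degrees of freedom
  (tau -> inf recovers BCCG); parameters (mu, sigma, nu, tau).

Interpretation: mu > 0 is the (approximate) median in the units of the
measurement, sigma > 0 is approximately the coefficient of variation,
nu is the skewness-correcting Box-Cox power, tau controls kurtosis.

Growth-chart column mapping: L = nu (the chart's lambda), M = mu,
S = sigma, plus tau where the family has one.

All densities include the exact normalizing constant for the truncation
of z to the region implied by y > 0 (|z| < 1/(sigma*|nu|) on one side),
so they integrate to one on (0, inf) for any parameter values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special

FAMILIES = ("BCCG", "BCPE", "BCT")

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


@dataclass(frozen=True)
class DistributionParams:
    """Parameters of one Box-Cox family at a single covariate value.

    ``tau`` must be ``None`` for BCCG and a positive number for
    BCPE (kurtosis power) and BCT (degrees of freedom).
    """

    family: str
    mu: float
    sigma: float
    nu: float
    tau: float | None = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; expected one of {FAMILIES}")
        if not self.mu > 0:
            raise ValueError("mu must be > 0")
        if not self.sigma > 0:
            raise ValueError("sigma must be > 0")
        if self.family == "BCCG":
            if self.tau is not None:
                raise ValueError("BCCG has no tau parameter")
        else:
            if self.tau is None or not self.tau > 0:
                raise ValueError(f"{self.family} requires tau > 0")


def box_cox_z(y, mu, sigma, nu):
    """Box-Cox z-score of y > 0 against (mu, sigma, nu).

    Continuous in nu at 0: computed via expm1 so the nu -> 0 limit
    agrees with the log form to machine precision.
    """
    y = np.asarray(y, dtype=float)
    if np.any(y <= 0):
        raise ValueError("y must be > 0")
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    nu = np.asarray(nu, dtype=float)
    logr = np.log(y / mu)
    nu_b, logr_b, sigma_b = np.broadcast_arrays(nu, logr, sigma)
    small = np.abs(nu_b) < 1e-12
    safe_nu = np.where(small, 1.0, nu_b)
    z = np.where(small, logr_b / sigma_b, np.expm1(nu_b * logr_b) / (safe_nu * sigma_b))
    return z


# ---------------------------------------------------------------------------
# symmetric kernels on z (mean 0; PE scaled to unit variance, t left standard)


def _pe_scale_c(tau):
    """c with c^2 = 2^(-2/tau) * Gamma(1/tau) / Gamma(3/tau); PE(0,1,tau) sd is 1."""
    tau = np.asarray(tau, dtype=float)
    return np.exp(0.5 * (special.gammaln(1.0 / tau) - special.gammaln(3.0 / tau)) - np.log(2.0) / tau)


def _kernel_logpdf(z, family, tau):
    z = np.asarray(z, dtype=float)
    if family == "BCCG":
        return -0.5 * z * z - _LOG_SQRT_2PI
    if family == "BCPE":
        tau = np.asarray(tau, dtype=float)
        c = _pe_scale_c(tau)
        return (
            np.log(tau)
            - np.log(c)
            - (1.0 + 1.0 / tau) * np.log(2.0)
            - special.gammaln(1.0 / tau)
            - 0.5 * np.abs(z / c) ** tau
        )
    if family == "BCT":
        df = np.asarray(tau, dtype=float)
        return (
            special.gammaln((df + 1.0) / 2.0)
            - special.gammaln(df / 2.0)
            - 0.5 * np.log(np.pi * df)
            - (df + 1.0) / 2.0 * np.log1p(z * z / df)
        )
    raise ValueError(f"unknown family {family!r}")


def _kernel_cdf(z, family, tau):
    z = np.asarray(z, dtype=float)
    if family == "BCCG":
        return special.ndtr(z)
    if family == "BCPE":
        tau = np.asarray(tau, dtype=float)
        c = _pe_scale_c(tau)
        s = special.gammainc(1.0 / tau, 0.5 * np.abs(z / c) ** tau)
        return 0.5 * (1.0 + np.sign(z) * s)
    if family == "BCT":
        return special.stdtr(np.asarray(tau, dtype=float), z)
    raise ValueError(f"unknown family {family!r}")


def _kernel_ppf(p, family, tau):
    p = np.asarray(p, dtype=float)
    if family == "BCCG":
        return special.ndtri(p)
    if family == "BCPE":
        tau = np.asarray(tau, dtype=float)
        c = _pe_scale_c(tau)
        q = 2.0 * p - 1.0
        mag = c * (2.0 * special.gammaincinv(1.0 / tau, np.abs(q))) ** (1.0 / tau)
        return np.sign(q) * mag
    if family == "BCT":
        return special.stdtrit(np.asarray(tau, dtype=float), p)
    raise ValueError(f"unknown family {family!r}")


def _trunc_cdf_at_bound(sigma, nu, family, tau):
    """F_T(1/(sigma*|nu|)); equals 1 when nu == 0 (no truncation)."""
    sigma = np.asarray(sigma, dtype=float)
    nu = np.asarray(nu, dtype=float)
    absnu = np.abs(nu)
    bound = np.where(absnu < 1e-12, np.inf, 1.0 / (sigma * np.maximum(absnu, 1e-12)))
    return np.where(np.isinf(bound), 1.0, _kernel_cdf(bound, family, tau))


# ---------------------------------------------------------------------------
# vectorized family functions (arrays of y and/or parameters)


def family_logpdf(y, mu, sigma, nu, tau, family):
    """Log-density; fully vectorized over y and parameters."""
    y = np.asarray(y, dtype=float)
    if np.any(y <= 0):
        raise ValueError("y must be > 0")
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    nu = np.asarray(nu, dtype=float)
    z = box_cox_z(y, mu, sigma, nu)
    logjac = nu * np.log(y / mu) - np.log(y) - np.log(sigma)
    lognorm = np.log(_trunc_cdf_at_bound(sigma, nu, family, tau))
    return logjac + _kernel_logpdf(z, family, tau) - lognorm


def family_cdf(y, mu, sigma, nu, tau, family):
    """Distribution function of the y > 0 truncated family."""
    z = box_cox_z(y, mu, sigma, nu)
    nu = np.asarray(nu, dtype=float)
    ftc = _trunc_cdf_at_bound(sigma, nu, family, tau)
    fz = _kernel_cdf(z, family, tau)
    # nu > 0: z is left-truncated at -1/(sigma*nu); nu <= 0: right-truncated.
    p = np.where(nu > 1e-12, (fz - (1.0 - ftc)) / ftc, fz / ftc)
    return np.clip(p, 0.0, 1.0)


def family_quantile(p, mu, sigma, nu, tau, family):
    """Quantile function (inverse of :func:`family_cdf`)."""
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("p must lie in (0, 1)")
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    nu = np.asarray(nu, dtype=float)
    ftc = _trunc_cdf_at_bound(sigma, nu, family, tau)
    pk = np.where(nu > 1e-12, p * ftc + (1.0 - ftc), p * ftc)
    t = _kernel_ppf(pk, family, tau)
    mu_b, sigma_b, nu_b, t_b = np.broadcast_arrays(mu, sigma, nu, t)
    small = np.abs(nu_b) < 1e-12
    safe_nu = np.where(small, 1.0, nu_b)
    arg = np.clip(sigma_b * nu_b * t_b, -1.0 + 1e-15, None)
    y = np.where(small, mu_b * np.exp(sigma_b * t_b), mu_b * np.exp(np.log1p(arg) / safe_nu))
    return y


def family_rvs(n, mu, sigma, nu, tau, family, seed):
    """Inverse-CDF sampling; reproducible for a fixed seed.

    Parameters may be scalars or length-n arrays (age-varying curves).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    u = rng.uniform(1e-12, 1.0 - 1e-12, size=int(n))
    return family_quantile(u, mu, sigma, nu, tau, family)


# ---------------------------------------------------------------------------
# thin object interface


def logpdf(y, params: DistributionParams):
    return family_logpdf(y, params.mu, params.sigma, params.nu, params.tau, params.family)


def pdf(y, params: DistributionParams):
    return np.exp(logpdf(y, params))


def cdf(y, params: DistributionParams):
    return family_cdf(y, params.mu, params.sigma, params.nu, params.tau, params.family)


def quantile(p, params: DistributionParams):
    return family_quantile(p, params.mu, params.sigma, params.nu, params.tau, params.family)


def rvs(n, params: DistributionParams, seed):
    return family_rvs(n, params.mu, params.sigma, params.nu, params.tau, params.family, seed)


def lms_centile(p, L, M, S, tau=None, family="BCCG"):
    """Centile from LMS-form parameters: y = M(1 + L*S*z_p)^(1/L).

    z_p is the kernel quantile -- the standard normal quantile for
    BCCG/LMS, the power-exponential quantile with power tau for BCPE,
    the t quantile for BCT.  Raises when the Box-Cox argument
    1 + L*S*z_p is non-positive (centile undefined).
    """
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("p must lie in (0, 1)")
    if not np.all(np.asarray(M, dtype=float) > 0) or not np.all(np.asarray(S, dtype=float) > 0):
        raise ValueError("M and S must be > 0")
    zp = _kernel_ppf(p, family, tau)
    L = np.asarray(L, dtype=float)
    S = np.asarray(S, dtype=float)
    arg = 1.0 + L * S * zp
    use_log = np.abs(L) < 1e-12
    if np.any((arg <= 0) & ~use_log):
        raise ValueError("centile undefined: 1 + L*S*z_p <= 0")
    with np.errstate(divide="ignore", invalid="ignore"):
        y = np.where(use_log, M * np.exp(S * zp), M * np.where(arg > 0, arg, 1.0) ** (1.0 / np.where(use_log, 1.0, L)))
    return y
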