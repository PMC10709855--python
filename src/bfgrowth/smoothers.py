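"""Smoothing constructions for age-varying distribution parameters.

Three smoother kinds, matching the candidate set evaluated for the
growth curves:

* ``ps``   -- penalized B-splines (P-splines): cubic B-spline basis on
  equally spaced interior knots with a second-order difference penalty.
* ``cs``   -- natural cubic smoothing spline: natural-spline basis with
  the exact integrated-squared-second-derivative roughness penalty.
* ``poly`` -- unpenalized polynomial of the requested degree.

Degrees-of-freedom convention (used throughout the package): the
``target_df`` of a smoother counts effective df *beyond the intercept*.
df = 0 is a constant, df = 1 a straight line, df >= 2 a penalized smooth
whose smoother-matrix trace is resolved to df + 1.

The covariate is age in days, rescaled internally to [0, 1] for
numerical conditioning; evaluation outside the fitted range extends the
curve linearly (with a warning at design time).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import BSpline
from scipy.linalg import cho_factor, cho_solve

SMOOTHER_KINDS = ("ps", "cs", "poly")


@dataclass
class SmootherSpec:
    kind: str
    target_df: int
    n_knots: int = 20          # interior knots (ps) / total knots (cs)
    degree: int = 3
    penalty_order: int = 2
    penalty_weight: float | None = None  # resolved lambda; None = unresolved

    def __post_init__(self) -> None:
        if self.kind not in SMOOTHER_KINDS:
            raise ValueError(f"unknown smoother kind {self.kind!r}")
        if self.target_df < 0:
            raise ValueError("target_df must be >= 0")
        if self.penalty_weight is not None and self.penalty_weight < 0:
            raise ValueError("penalty weight must be >= 0")

    @property
    def basis_size(self) -> int:
        if self.kind == "ps":
            return self.n_knots + self.degree + 1
        if self.kind == "cs":
            return self.n_knots
        return self.target_df + 1


@dataclass
class ParamCurve:
    """One distribution parameter as a smooth function of age.

    Coefficients live on the link scale; ``value`` applies the inverse
    link.  ``x_range`` is the fitted age range in days.
    """

    spec: SmootherSpec
    coef: np.ndarray
    link: str  # "log" | "identity"
    x_range: tuple[float, float]
    edf: float

    def linear_predictor(self, age_days) -> np.ndarray:
        t = np.atleast_1d(np.asarray(age_days, dtype=float))
        lo, hi = self.x_range
        span = max(hi - lo, 1e-12)
        x = (t - lo) / span
        xc = np.clip(x, 0.0, 1.0)
        B = design_matrix(xc, self.spec, warn_outside=False)
        eta = B @ self.coef
        # linear extension beyond the fitted range
        out_lo, out_hi = x < 0.0, x > 1.0
        if np.any(out_lo) or np.any(out_hi):
            eps = 1e-4
            for mask, x0 in ((out_lo, 0.0), (out_hi, 1.0)):
                if not np.any(mask):
                    continue
                b0 = design_matrix(np.array([x0, x0 + (eps if x0 == 0.0 else -eps)]), self.spec, warn_outside=False)
                f0, f1 = b0 @ self.coef
                slope = (f1 - f0) / (eps if x0 == 0.0 else -eps)
                eta[mask] = f0 + slope * (x[mask] - x0)
        return eta

    def value(self, age_days) -> np.ndarray:
        eta = self.linear_predictor(age_days)
        return np.exp(eta) if self.link == "log" else eta


# ---------------------------------------------------------------------------
# bases and penalties (covariate already scaled to [0, 1])


def _ps_knots(spec: SmootherSpec) -> np.ndarray:
    # Eilers-Marx P-spline: one uniform knot grid extended degree steps
    # past each boundary, so linear coefficient sequences (hence linear
    # functions) lie exactly in the difference-penalty null space.
    k = spec.degree
    h = 1.0 / (spec.n_knots + 1)
    return np.linspace(-k * h, 1.0 + k * h, spec.n_knots + 2 + 2 * k)


def _cs_knots(spec: SmootherSpec) -> np.ndarray:
    return np.linspace(0.0, 1.0, spec.n_knots)


def _natural_spline_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Natural cubic spline basis: 1, x, then K-2 truncated-cubic combinations."""
    K = len(knots)
    xK, xK1 = knots[-1], knots[-2]

    def d(j):
        return (np.clip(x - knots[j], 0, None) ** 3 - np.clip(x - xK, 0, None) ** 3) / (xK - knots[j])

    cols = [np.ones_like(x), x]
    dK1 = d(K - 2)
    for j in range(K - 2):
        cols.append(d(j) - dK1)
    return np.column_stack(cols)


def _natural_spline_penalty(knots: np.ndarray) -> np.ndarray:
    """Exact Omega_{jl} = integral of N_j'' N_l'' (second derivatives are
    piecewise linear, so Simpson per inter-knot interval is exact)."""
    K = len(knots)
    xK, xK1 = knots[-1], knots[-2]

    def d2(j, x):
        return 6.0 * (np.clip(x - knots[j], 0, None) - np.clip(x - xK, 0, None)) / (xK - knots[j])

    def basis_d2(x):
        cols = [np.zeros_like(x), np.zeros_like(x)]
        dK1 = d2(K - 2, x)
        for j in range(K - 2):
            cols.append(d2(j, x) - dK1)
        return np.column_stack(cols)

    m = K
    Omega = np.zeros((m, m))
    for a, b in zip(knots[:-1], knots[1:]):
        xs = np.array([a, 0.5 * (a + b), b])
        w = (b - a) / 6.0 * np.array([1.0, 4.0, 1.0])
        D = basis_d2(xs)
        Omega += D.T @ (w[:, None] * D)
    return Omega


def design_matrix(x, spec: SmootherSpec, warn_outside: bool = True) -> np.ndarray:
    """Design matrix for covariate values x in [0, 1]."""
    x = np.asarray(x, dtype=float)
    if warn_outside and (np.any(x < 0) or np.any(x > 1)):
        warnings.warn("covariate outside fitted range; basis extended linearly", stacklevel=2)
    xc = np.clip(x, 0.0, 1.0)
    if spec.kind == "ps":
        t = _ps_knots(spec)
        return BSpline.design_matrix(xc, t, spec.degree, extrapolate=True).toarray()
    if spec.kind == "cs":
        return _natural_spline_basis(xc, _cs_knots(spec))
    return np.vander(xc, spec.target_df + 1, increasing=True)


def penalty_matrix(spec: SmootherSpec) -> np.ndarray:
    m = spec.basis_size
    if spec.kind == "ps":
        D = np.diff(np.eye(m), n=spec.penalty_order, axis=0)
        return D.T @ D
    if spec.kind == "cs":
        return _natural_spline_penalty(_cs_knots(spec))
    return np.zeros((m, m))


# ---------------------------------------------------------------------------
# penalized weighted least squares with edf control


def _edf(B, w, P, lam) -> float:
    BtWB = B.T @ (w[:, None] * B)
    A = BtWB + lam * P
    try:
        c = cho_factor(A + 1e-12 * np.eye(A.shape[0]))
        return float(np.trace(cho_solve(c, BtWB)))
    except np.linalg.LinAlgError:
        return float(np.trace(np.linalg.pinv(A) @ BtWB))


def resolve_df(x, weights, spec: SmootherSpec, target_df: int | None = None) -> float:
    """Penalty weight lambda such that trace(smoother matrix) = target_df + 1.

    Monotone bisection on log-lambda; the trace is strictly decreasing
    in lambda.  target_df must lie between the penalty null-space
    dimension minus one (1: constant + linear) and basis_size - 1.
    """
    if target_df is None:
        target_df = spec.target_df
    if spec.kind == "poly":
        return 0.0
    x = np.asarray(x, dtype=float)
    w = np.asarray(weights, dtype=float)
    B = design_matrix(x, spec, warn_outside=False)
    P = penalty_matrix(spec)
    m = spec.basis_size
    target = target_df + 1.0
    if target >= m:
        if target > m:
            raise ValueError(f"target df {target_df} unreachable; achievable range is [1, {m - 1}]")
        return 0.0
    if target < 2.0:
        raise ValueError(f"target df {target_df} below penalty null space; achievable range is [1, {m - 1}]")
    lo, hi = -12.0, 8.0
    e_lo, e_hi = _edf(B, w, P, 10.0 ** lo), _edf(B, w, P, 10.0 ** hi)
    if not (e_hi - 1e-3 <= target <= e_lo + 1e-3):
        raise ValueError(
            f"target df {target_df} unreachable: achievable edf range "
            f"[{e_hi - 1:.3f}, {e_lo - 1:.3f}] for this design"
        )
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if _edf(B, w, P, 10.0 ** mid) > target:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-9:
            break
    return 10.0 ** (0.5 * (lo + hi))


def fit_weighted(x, y, weights, spec: SmootherSpec, x_range=(0.0, 1.0), link="identity") -> ParamCurve:
    """Penalized weighted least squares fit of y on the smoother basis.

    x is the covariate already scaled to [0, 1]; ``x_range`` records the
    corresponding age range in days for later evaluation.  df = 0 and
    df = 1 short-circuit to the constant and straight-line fits.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(weights, dtype=float)
    if not (len(x) == len(y) == len(w)):
        raise ValueError("x, y, weights must have equal length")
    if np.any(w < 0) or not np.any(w > 0):
        raise ValueError("weights must be >= 0 and not all zero")

    if spec.target_df == 0:
        coef = np.array([np.sum(w * y) / np.sum(w)])
        used = replace(spec, kind="poly", target_df=0, penalty_weight=0.0)
        return ParamCurve(used, coef, link, x_range, edf=1.0)
    if spec.target_df == 1 and spec.kind != "poly":
        B = np.column_stack([np.ones_like(x), x])
        coef = _solve_pwls(B, y, w, np.zeros((2, 2)), 0.0)
        used = replace(spec, kind="poly", target_df=1, penalty_weight=0.0)
        return ParamCurve(used, coef, link, x_range, edf=2.0)

    B = design_matrix(x, spec, warn_outside=False)
    P = penalty_matrix(spec)
    if spec.kind == "poly":
        lam = 0.0
    elif spec.penalty_weight is not None:
        lam = spec.penalty_weight
    else:
        lam = resolve_df(x, w, spec)
    coef = _solve_pwls(B, y, w, P, lam)
    edf = _edf(B, w, P, lam) if spec.kind != "poly" else float(B.shape[1])
    return ParamCurve(replace(spec, penalty_weight=lam), coef, link, x_range, edf=edf)


def _solve_pwls(B, y, w, P, lam) -> np.ndarray:
    A = B.T @ (w[:, None] * B) + lam * P
    b = B.T @ (w * y)
    try:
        return cho_solve(cho_factor(A), b)
    except np.linalg.LinAlgError:
        warnings.warn("singular penalized system; ridge fallback applied", stacklevel=2)
        return np.linalg.solve(A + 1e-8 * np.trace(A) / A.shape[0] * np.eye(A.shape[0]), b)
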