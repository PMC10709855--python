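"""Synthetic MICS-like survey tables with known ground truth.

Generates child-level records that mimic the structure of a MICS round-6
under-six-months extract: raw 24-hour feeding recall items (nine liquid
and fifteen food binaries plus the still-breastfed flag), two-week
illness recall items, household composition counts, eligibility
booleans, and weight/height drawn from Box-Cox families with known
age-varying parameter curves.  Every derived indicator (exclusive
breastfeeding, severe illness, household congestion) is re-derivable
from the raw variables it generates, so the selection algorithms can be
tested against analytically known yields.

Default truth curves are log-linear in age and anchored to the weekly
means of the surveyed Pakistani sample (boys' weight rising from about
3.26 kg in week 1 to 6.92 kg in week 26, and correspondingly for girls
and for height), with the per-curve kurtosis powers tau fixed at the
values fitted for the four published curves.  Selection-criterion
prevalences default to values whose product reproduces the published
overall yield (3,655 of 11,478 children, about 31.8%).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .distributions import family_quantile

LIQUID_COLS = [f"x{i}" for i in range(1, 10)]
FOOD_COLS = [f"y{i}" for i in range(1, 16)]

PROVINCES = ("KPK", "Punjab", "Sindh", "Balochistan")


@dataclass
class CurveTruth:
    """True (mu, sigma, nu, tau) curves for one measure/sex.

    mu(t) = mu0 * exp(rate * t) with t in days -- strictly increasing,
    linear on the log-link scale.  sigma and nu are constant.
    """

    family: str
    mu0: float
    mu_rate: float
    sigma: float
    nu: float
    tau: float | None

    def mu(self, age_days):
        return self.mu0 * np.exp(self.mu_rate * np.asarray(age_days, dtype=float))

    def params_at(self, age_days):
        t = np.asarray(age_days, dtype=float)
        one = np.ones_like(t)
        return self.mu(t), self.sigma * one, self.nu * one, self.tau


@dataclass
class TruthSpec:
    """Ground truth for the generator: anthropometry curves + prevalences."""

    curves: dict  # (measure, sex) -> CurveTruth
    p_ebf: float = 0.55
    p_severe_illness: float = 0.08
    p_congested: float = 0.09
    p_singleton: float = 0.985
    p_fullterm: float = 0.90
    p_birth_order_le4: float = 0.80
    p_nonsmoking: float = 0.97
    p_male: float = 0.5
    province_probs: dict = field(
        default_factory=lambda: {"KPK": 0.230, "Punjab": 0.401, "Sindh": 0.224, "Balochistan": 0.145}
    )
    p_urban: float = 0.236
    p_missing_weight: float = 0.0315
    p_missing_height: float = 0.0383
    deprivation_correlation: float = 0.0  # shared latent factor for EBF/illness/congestion
    age_max_days: int = 182

    def validate(self) -> None:
        for name in (
            "p_ebf",
            "p_severe_illness",
            "p_congested",
            "p_singleton",
            "p_fullterm",
            "p_birth_order_le4",
            "p_nonsmoking",
            "p_male",
            "p_urban",
            "p_missing_weight",
            "p_missing_height",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not -0.999 < self.deprivation_correlation < 0.999:
            raise ValueError("deprivation_correlation must be in (-1, 1)")
        if abs(sum(self.province_probs.values()) - 1.0) > 1e-9:
            raise ValueError("province probabilities must sum to 1")
        t = np.arange(0, self.age_max_days + 1)
        for key, c in self.curves.items():
            if np.any(c.mu(t) <= 0) or c.sigma <= 0:
                raise ValueError(f"curve {key}: mu(t) and sigma must be > 0")
            if c.tau is not None and c.tau <= 0:
                raise ValueError(f"curve {key}: tau must be > 0")

    def to_yaml(self, path) -> None:
        payload = {
            "curves": {
                f"{m}/{s}": {
                    "family": c.family,
                    "mu0": float(c.mu0),
                    "mu_rate": float(c.mu_rate),
                    "sigma": float(c.sigma),
                    "nu": float(c.nu),
                    "tau": None if c.tau is None else float(c.tau),
                }
                for (m, s), c in self.curves.items()
            },
            "prevalences": {
                k: getattr(self, k)
                for k in (
                    "p_ebf",
                    "p_severe_illness",
                    "p_congested",
                    "p_singleton",
                    "p_fullterm",
                    "p_birth_order_le4",
                    "p_nonsmoking",
                    "p_male",
                    "p_urban",
                    "p_missing_weight",
                    "p_missing_height",
                    "deprivation_correlation",
                )
            },
            "province_probs": dict(self.province_probs),
            "age_max_days": self.age_max_days,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh)

    @classmethod
    def from_yaml(cls, path) -> "TruthSpec":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        curves = {}
        for key, cv in payload["curves"].items():
            m, s = key.split("/")
            curves[(m, s)] = CurveTruth(**cv)
        spec = cls(curves=curves, **payload.get("prevalences", {}))
        spec.province_probs = payload.get("province_probs", spec.province_probs)
        spec.age_max_days = payload.get("age_max_days", spec.age_max_days)
        spec.validate()
        return spec


def default_truth() -> TruthSpec:
    """Truth anchored to the surveyed weekly means and fitted tau values.

    Log-linear medians pass within the required tolerance of the weekly
    anchor means (boys weight 3.26 kg week 1 / 6.92 kg week 26; girls
    weight 3.22 / 6.19; boys height 48.74 / 65.07 cm; girls height
    48.87 / 63.54).  Constant sigma on the coefficient-of-variation
    scale of the weekly summaries; nu constant at 1; tau per curve at
    the fitted values 1.660 / 1.448 / 1.189 / 1.115.
    """

    def loglinear(v1, v26):
        # weekly anchors at mid-week ages 3 and 178 days
        rate = np.log(v26 / v1) / 175.0
        return v1 * np.exp(-3.0 * rate), rate

    curves = {}
    for (measure, sex), (v1, v26, sigma, tau) in {
        ("weight", "male"): (3.26, 6.92, 0.185, 1.660418),
        ("weight", "female"): (3.22, 6.19, 0.185, 1.448022),
        ("height", "male"): (48.74, 65.07, 0.055, 1.188859),
        ("height", "female"): (48.87, 63.54, 0.055, 1.114607),
    }.items():
        mu0, rate = loglinear(v1, v26)
        curves[(measure, sex)] = CurveTruth(family="BCPE", mu0=mu0, mu_rate=rate, sigma=sigma, nu=1.0, tau=tau)
    spec = TruthSpec(curves=curves)
    spec.validate()
    return spec


def sample_anthro(ages, truth: TruthSpec, measure: str, sex: str, seed) -> np.ndarray:
    """Draw one measurement per age from the truth family (inverse CDF)."""
    c = truth.curves[(measure, sex)]
    t = np.asarray(ages, dtype=float)
    rng = np.random.default_rng(seed)
    u = rng.uniform(1e-12, 1 - 1e-12, size=t.shape)
    mu, sigma, nu, tau = c.params_at(t)
    return family_quantile(u, mu, sigma, nu, tau, c.family)


def _correlated_bernoulli(rng, probs, rho, n):
    """Columns of indicators hitting given marginal prevalences; optional
    shared latent 'deprivation' factor (Gaussian copula), rho = 0 means
    fully independent criteria."""
    from scipy.special import ndtr, ndtri

    k = len(probs)
    if rho == 0.0:
        u = rng.random((n, k))
        return u < np.asarray(probs)[None, :]
    g = rng.standard_normal(n)
    eps = rng.standard_normal((n, k))
    lat = rho * g[:, None] + np.sqrt(1 - rho * rho) * eps
    return ndtr(lat) < np.asarray(probs)[None, :]


def generate(n: int, truth: TruthSpec, seed) -> pd.DataFrame:
    """Generate an n-row MICS-like child table.

    Ages uniform on integer days 0..age_max_days; raw feeding, illness
    and household variables are constructed to be exactly consistent
    with latent EBF / severe-illness / congestion indicators drawn at
    the configured prevalences (the latent columns are included with an
    ``sim_`` prefix for truth-recovery tests; the selection algorithms
    never read them).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    truth.validate()
    rng = np.random.default_rng(seed)

    age = rng.integers(0, truth.age_max_days + 1, size=n)
    male = rng.random(n) < truth.p_male
    sex = np.where(male, "male", "female")
    provinces = list(truth.province_probs)
    province = rng.choice(provinces, size=n, p=[truth.province_probs[p] for p in provinces])
    area = np.where(rng.random(n) < truth.p_urban, "urban", "rural")

    # latent selection criteria (independent unless correlation enabled)
    crit = _correlated_bernoulli(
        rng,
        [truth.p_ebf, truth.p_severe_illness, truth.p_congested],
        truth.deprivation_correlation,
        n,
    )
    ebf, severe, congested = crit[:, 0], crit[:, 1], crit[:, 2]

    df = pd.DataFrame(
        {
            "id": np.arange(1, n + 1),
            "age_days": age.astype(int),
            "sex": sex,
            "province": province,
            "area": area,
        }
    )

    # --- feeding recall consistent with EBF status ------------------------
    Z = np.ones(n, dtype=float)
    x = np.zeros((n, 9))
    y = np.zeros((n, 15))
    non = ~ebf
    # among non-EBF children: most still breastfed but mixed-fed, rest weaned
    weaned = non & (rng.random(n) < 0.3)
    Z[weaned] = 0.0
    mixed = non & ~weaned
    x[mixed] = rng.random((int(mixed.sum()), 9)) < 0.15
    y[mixed] = rng.random((int(mixed.sum()), 15)) < 0.10
    # mixed-fed must have consumed something besides breast milk
    none_given = mixed & (x.sum(1) + y.sum(1) == 0)
    x[none_given, 0] = 1.0
    x[weaned] = rng.random((int(weaned.sum()), 9)) < 0.3
    y[weaned] = rng.random((int(weaned.sum()), 15)) < 0.3
    df["still_breastfed"] = Z
    for j, colname in enumerate(LIQUID_COLS):
        df[colname] = x[:, j]
    for j, colname in enumerate(FOOD_COLS):
        df[colname] = y[:, j]

    # --- illness recall consistent with severe-illness status -------------
    fever = (rng.random(n) < 0.15).astype(float)
    cough = (rng.random(n) < 0.20).astype(float)
    breath = (rng.random(n) < 0.05).astype(float)
    diarrhea = (rng.random(n) < 0.25).astype(float)
    diarrhea[severe] = 1.0
    other = fever + cough + breath > 0
    fever[severe & ~other] = 1.0
    mild = ~severe & (diarrhea == 1)
    fever[mild] = 0.0
    cough[mild] = 0.0
    breath[mild] = 0.0
    df["diarrhea"] = diarrhea
    df["fever"] = fever
    df["cough"] = cough
    df["breathing_difficulty"] = breath

    # --- household composition consistent with congestion status ----------
    rooms = rng.integers(1, 5, size=n)
    max_ok = 2 * rooms
    adults = np.where(
        congested,
        max_ok + rng.integers(1, 5, size=n),
        1 + rng.integers(0, max_ok, size=n) % max_ok,
    )
    under5 = rng.integers(1, 4, size=n)
    age5_17 = rng.integers(0, 4, size=n)
    df["hh_members"] = (adults + under5 + age5_17).astype(float)
    df["under5"] = under5.astype(float)
    df["age5_17"] = age5_17.astype(float)
    df["sleeping_rooms"] = rooms.astype(float)

    # --- eligibility booleans ---------------------------------------------
    df["singleton"] = rng.random(n) < truth.p_singleton
    df["full_term"] = rng.random(n) < truth.p_fullterm
    bo_ok = rng.random(n) < truth.p_birth_order_le4
    df["birth_order"] = np.where(bo_ok, rng.integers(1, 5, size=n), 5 + rng.integers(0, 4, size=n))
    df["mother_smokes"] = ~(rng.random(n) < truth.p_nonsmoking)

    # --- anthropometry ------------------------------------------------------
    for measure, col in (("weight", "weight_kg"), ("height", "height_cm")):
        vals = np.empty(n)
        for s in ("male", "female"):
            m = sex == s
            c = truth.curves[(measure, s)]
            mu, sg, nu, tau = c.params_at(age[m])
            u = rng.uniform(1e-12, 1 - 1e-12, size=int(m.sum()))
            vals[m] = family_quantile(u, mu, sg, nu, tau, c.family)
        p_miss = truth.p_missing_weight if measure == "weight" else truth.p_missing_height
        if p_miss > 0:
            vals[rng.random(n) < p_miss] = np.nan
        df[col] = vals

    # latent truth columns for tests / truth echo
    df["sim_ebf"] = ebf
    df["sim_severe_illness"] = severe
    df["sim_congested"] = congested
    return df
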