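"""Centile tables and charts from fitted models, and comparison with an
external reference (e.g. the WHO standards).

A centile table records, for each age on the reporting grid (weekly by
default), the fitted lambda/mu/sigma/tau values and the requested
percentiles of the fitted family.  Comparison with a reference chart is
cellwise (own minus reference) on a shared age x percentile grid; where
the reference is tabulated at 175 and 205 days only, the 180-day
(six-month) values are obtained by linear interpolation between those
two ages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_PERCENTILES = (3, 5, 10, 25, 50, 75, 90, 97)
DEFAULT_AGES = tuple(range(0, 183, 7))  # weekly, 0-26 weeks


def _plabel(p) -> str:
    return f"P{p:g}"


@dataclass
class CentileTable:
    """Age grid x percentiles plus fitted lambda/mu/sigma/tau columns."""

    measure: str
    sex: str
    ages: np.ndarray
    lam: np.ndarray
    mu: np.ndarray
    sigma: np.ndarray
    tau: np.ndarray
    percentiles: tuple
    values: np.ndarray  # shape (n_ages, n_percentiles)

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.ages), len(self.percentiles)):
            raise ValueError("values shape must be (n_ages, n_percentiles)")
        if np.any(np.diff(self.values, axis=1) <= 0):
            raise ValueError("percentile values must be strictly increasing in p at every age")

    def frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"age_days": self.ages, "lambda": self.lam, "mu": self.mu, "sigma": self.sigma, "tau": self.tau})
        for j, p in enumerate(self.percentiles):
            df[_plabel(p)] = self.values[:, j]
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, measure: str = "", sex: str = "") -> "CentileTable":
        pcols = [c for c in df.columns if c.startswith("P")]
        percs = tuple(float(c[1:]) for c in pcols)
        return cls(
            measure=measure,
            sex=sex,
            ages=df["age_days"].to_numpy(dtype=float),
            lam=df["lambda"].to_numpy(dtype=float),
            mu=df["mu"].to_numpy(dtype=float),
            sigma=df["sigma"].to_numpy(dtype=float),
            tau=df["tau"].to_numpy(dtype=float),
            percentiles=percs,
            values=df[pcols].to_numpy(dtype=float),
        )


def make_centile_table(
    model,
    ages=DEFAULT_AGES,
    percentiles=DEFAULT_PERCENTILES,
    measure: str = "",
    sex: str = "",
) -> CentileTable:
    """Evaluate the fitted parameter curves on an age grid and apply the
    family quantile for each requested percentile."""
    if not model.converged:
        raise ValueError("model did not converge; refusing to tabulate centiles")
    ages = np.asarray(ages, dtype=float)
    lo, hi = model.x_range
    if np.any(ages < lo - 1e-9) or np.any(ages > hi + 1e-9):
        import warnings

        warnings.warn("age grid extends beyond the fitted range; centiles extrapolated", stacklevel=2)
    mu, sigma, nu, tau = model.params_at(ages)
    vals = np.column_stack([model.quantile(ages, p / 100.0) for p in percentiles])
    tau_col = tau if tau is not None else np.full(len(ages), np.nan)
    return CentileTable(
        measure=measure,
        sex=sex,
        ages=ages,
        lam=np.asarray(nu, dtype=float),
        mu=np.asarray(mu, dtype=float),
        sigma=np.asarray(sigma, dtype=float),
        tau=np.asarray(tau_col, dtype=float),
        percentiles=tuple(percentiles),
        values=vals,
    )


def interpolate_reference(ref, target_age: float = 180.0, bracket=(175.0, 205.0)) -> pd.Series:
    """Reference percentile values at ``target_age`` by linear
    interpolation between the bracketing tabulated ages (175/205 days
    for the six-month point of the WHO tables)."""
    lo, hi = bracket
    tab = ref.table.set_index("age_days")
    for a in (lo, hi):
        if a not in tab.index:
            raise ValueError(f"reference table lacks bracketing age {a}")
    frac = (target_age - lo) / (hi - lo)
    v_lo = tab.loc[lo]
    v_hi = tab.loc[hi]
    out = v_lo + frac * (v_hi - v_lo)
    out.name = target_age
    return out


@dataclass
class ComparisonTable:
    """Cellwise own-minus-reference differences on a shared grid."""

    ages: np.ndarray
    percentile_labels: list
    own: pd.DataFrame
    reference: pd.DataFrame
    difference: pd.DataFrame = field(init=False)

    def __post_init__(self) -> None:
        self.difference = self.own - self.reference

    def max_abs_gap(self) -> pd.Series:
        return self.difference.abs().max(axis=0)


def compare_tables(own: CentileTable, ref: pd.DataFrame) -> ComparisonTable:
    """Compare a fitted centile table with reference values.

    ``ref`` must be indexed by age_days with percentile-label columns
    covering the own table's grid (error names any missing cells)."""
    own_df = own.frame().set_index("age_days")
    own_cols = {_plabel(p): p for p in own.percentiles}
    shared = [c for c in own_cols if c in ref.columns]
    missing_cols = [c for c in own_cols if c not in ref.columns]
    missing_ages = [a for a in own_df.index if a not in ref.index]
    if missing_cols or missing_ages:
        raise ValueError(
            f"reference grid mismatch: missing percentile columns {missing_cols}, missing ages {missing_ages}"
        )
    o = own_df[shared]
    r = ref.loc[own_df.index, shared]
    return ComparisonTable(ages=own_df.index.to_numpy(), percentile_labels=shared, own=o, reference=r)


def plot_charts(own: CentileTable, ref: pd.DataFrame | None = None, path=None, ref_label="reference"):
    """Centile chart: own centiles as solid lines, reference dashed.

    Returns the output path.  Deterministic styling so repeated runs
    produce identical files.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ref is not None and hasattr(ref, "table"):  # WHOReference
        if ref.measure and own.measure and ref.measure != own.measure:
            raise ValueError(f"measure mismatch: chart is {own.measure!r}, reference is {ref.measure!r}")
        ref = ref.table.set_index("age_days")
    if ref is not None and len(ref) == 0:
        ref = None
    fig, ax = plt.subplots(figsize=(7, 5))
    weeks = own.ages / 7.0
    for j, p in enumerate(own.percentiles):
        ax.plot(weeks, own.values[:, j], "-", lw=1.2, label=_plabel(p))
    if ref is not None:
        for c in ref.columns:
            ax.plot(ref.index.to_numpy() / 7.0, ref[c], "--", lw=1.0, color="gray")
    unit = {"weight": "kg", "height": "cm"}.get(own.measure, "")
    ax.set_xlabel("age (weeks)")
    ax.set_ylabel(f"{own.measure} ({unit})" if unit else own.measure)
    ax.set_title(f"{own.measure}-for-age, {own.sex}" + (f" (dashed: {ref_label})" if ref is not None else ""))
    ax.legend(fontsize=7, ncol=2)
    fig.tight_layout()
    if path is None:
        raise ValueError("path is required")
    fig.savefig(path, dpi=100, metadata={"Software": None} if str(path).endswith(".png") else None)
    plt.close(fig)
    return path
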