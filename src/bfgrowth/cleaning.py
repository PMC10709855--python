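"""Screening of the selected sample before curve fitting.

Weight and height are cleaned as *separate* analysis files (a record
missing weight can still contribute to the height chart), mirroring the
distinct final sample sizes of the two charts.

Two stages:

1. ``drop_incomplete`` removes records with missing sex, a missing or
   non-positive measurement, or an age outside the study window.
2. ``flag_outliers`` applies a hard biological-plausibility window and
   then a per-sex provisional fit on the normal scale -- a low-df
   penalized-spline median curve with an age-varying spread estimated
   from absolute residuals -- flagging records with |z| above the cutoff
   (default 4).

The provisional-fit rule is a configurable screening device in the
spirit of standard anthropometric flagging; no single rule can be
claimed to reproduce any particular survey's post-cleaning counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .smoothers import SmootherSpec, fit_weighted

MEASURE_COLUMNS = {"weight": "weight_kg", "height": "height_cm"}


def _fit_with_fallback(x, y, w, df, x_range):
    """Provisional fit at the requested df, stepping down on degenerate designs."""
    for d in range(df, -1, -1):
        try:
            return fit_weighted(x, y, w, SmootherSpec("ps", d), x_range=x_range)
        except (ValueError, np.linalg.LinAlgError):
            continue
    coef = np.array([float(np.average(y, weights=w))])
    return fit_weighted(x, np.full_like(np.asarray(y, dtype=float), coef[0]), w, SmootherSpec("ps", 0), x_range=x_range)


@dataclass
class CleanConfig:
    weight_window: tuple = (0.5, 15.0)
    height_window: tuple = (35.0, 95.0)
    age_window: tuple = (0, 182)
    z_cutoff: float = 4.0
    provisional_df: int = 3
    min_per_sex: int = 50

    def __post_init__(self) -> None:
        for name in ("weight_window", "height_window", "age_window"):
            lo, hi = getattr(self, name)
            if hi <= lo:
                raise ValueError(f"{name} is empty")
        if self.z_cutoff <= 0:
            raise ValueError("z_cutoff must be > 0")

    def window(self, measure: str) -> tuple:
        return self.weight_window if measure == "weight" else self.height_window


def drop_incomplete(records: pd.DataFrame, measure: str, config: CleanConfig | None = None) -> pd.DataFrame:
    """Remove records unusable for the given measure's analysis file."""
    if measure not in MEASURE_COLUMNS:
        raise ValueError("measure must be 'weight' or 'height'")
    config = config or CleanConfig()
    col = MEASURE_COLUMNS[measure]
    age = pd.to_numeric(records["age_days"], errors="coerce")
    val = pd.to_numeric(records[col], errors="coerce")
    lo, hi = config.age_window
    keep = (
        records["sex"].isin(["male", "female"])
        & val.notna()
        & (val > 0)
        & age.notna()
        & age.between(lo, hi)
    )
    return records.loc[keep].copy()


def flag_outliers(
    records: pd.DataFrame, measure: str, config: CleanConfig | None = None, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-stage outlier screen; returns (kept, flagged).

    kept and flagged partition the input; flagged rows carry a
    ``flag_reason`` column.  Deterministic for fixed config (the seed is
    accepted for interface uniformity; no randomness is used).
    """
    if measure not in MEASURE_COLUMNS:
        raise ValueError("measure must be 'weight' or 'height'")
    config = config or CleanConfig()
    col = MEASURE_COLUMNS[measure]
    y = pd.to_numeric(records[col], errors="coerce")
    age = pd.to_numeric(records["age_days"], errors="coerce").astype(float)

    lo, hi = config.window(measure)
    reason = pd.Series("", index=records.index)
    window_bad = ~y.between(lo, hi)
    reason[window_bad] = "plausibility_window"

    for sex in ("male", "female"):
        m = (records["sex"] == sex) & ~window_bad
        n = int(m.sum())
        if n == 0:
            continue
        if n < config.min_per_sex:
            warnings.warn(
                f"only {n} {sex} records; provisional-fit outlier stage skipped", stacklevel=2
            )
            continue
        t = age[m].to_numpy()
        ty = y[m].to_numpy()
        t0, t1 = float(t.min()), float(max(t.max(), t.min() + 1))
        x = (t - t0) / (t1 - t0)
        w = np.ones_like(x)
        # cap smooth complexity by the support of distinct ages
        df_cap = max(0, min(config.provisional_df, len(np.unique(t)) - 1))
        med = _fit_with_fallback(x, ty, w, df_cap, (t0, t1))
        resid = ty - med.linear_predictor(t)
        abs_res = np.abs(resid)
        spread_curve = _fit_with_fallback(x, abs_res * np.sqrt(np.pi / 2.0), w, max(0, df_cap - 1), (t0, t1))
        spread = spread_curve.linear_predictor(t)
        floor = 1e-8 * max(float(np.median(np.abs(ty))), 1.0)
        spread = np.maximum(spread, floor)
        z = resid / spread
        bad = np.abs(z) > config.z_cutoff
        idx = records.index[m][bad]
        reason[idx] = np.where(reason[idx] == "", "provisional_z", reason[idx] + "+provisional_z")

    flagged_mask = reason != ""
    kept = records.loc[~flagged_mask].copy()
    flagged = records.loc[flagged_mask].copy()
    flagged["flag_reason"] = reason[flagged_mask]
    return kept, flagged
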