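"""Tabular I/O, survey variable mapping, and run configuration.

The pipeline consumes a canonical CSV child table.  Survey extracts use
their native column names (for a MICS-6 file: CA1 for diarrhea, CA14
fever, CA16 cough, CA17 breathing difficulty, BD3 still-breastfed, HH48
household members, HH51 under-5 count, HH52 5-17 count, HC3 sleeping
rooms, plus nine liquid and fifteen food recall items); a
:class:`VariableMap` renames them to the canonical fields.  Survey
don't-know sentinel codes (8/9) in binary items are stored as missing,
never as "No" -- downstream modules decide their treatment.

Ages are stored in days (integer); weeks = floor(days/7) for reporting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .synthetic import FOOD_COLS, LIQUID_COLS

#: canonical binary survey items subject to DK sentinel codes
BINARY_FIELDS = LIQUID_COLS + FOOD_COLS + [
    "still_breastfed",
    "diarrhea",
    "fever",
    "cough",
    "breathing_difficulty",
]

NUMERIC_FIELDS = BINARY_FIELDS + [
    "age_days",
    "weight_kg",
    "height_cm",
    "hh_members",
    "under5",
    "age5_17",
    "sleeping_rooms",
    "birth_order",
]

DK_SENTINELS = (8.0, 9.0)


def default_mics_map() -> dict:
    """Canonical field -> MICS-6 source column."""
    m = {
        "diarrhea": "CA1",
        "fever": "CA14",
        "cough": "CA16",
        "breathing_difficulty": "CA17",
        "still_breastfed": "BD3",
        "hh_members": "HH48",
        "under5": "HH51",
        "age5_17": "HH52",
        "sleeping_rooms": "HC3",
    }
    for c in LIQUID_COLS + FOOD_COLS:
        m[c] = c
    return m


@dataclass
class VariableMap:
    """Bijective mapping canonical field -> source column name."""

    mapping: dict = field(default_factory=default_mics_map)

    def __post_init__(self) -> None:
        sources = list(self.mapping.values())
        if len(set(sources)) != len(sources):
            dupes = sorted({s for s in sources if sources.count(s) > 1})
            raise ValueError(f"source column(s) mapped twice: {dupes}")

    def inverse(self) -> dict:
        return {v: k for k, v in self.mapping.items()}

    @classmethod
    def from_yaml(cls, path) -> "VariableMap":
        with open(path) as fh:
            return cls(mapping=yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.mapping, fh)


@dataclass
class RunConfig:
    """Run-wide settings; defaults reflect the study's criteria."""

    seed: int = 0
    age_max_days: int = 182
    max_adults_per_room: float = 2.0
    max_birth_order: int = 4
    missing_policy: str = "exclude"
    df_search_range: tuple = (0, 3)
    percentiles: tuple = (3, 5, 10, 25, 50, 75, 90, 97)
    weight_window: tuple = (0.5, 15.0)
    height_window: tuple = (35.0, 95.0)
    outlier_z_cutoff: float = 4.0
    out_dir: str = "."

    def __post_init__(self) -> None:
        if self.age_max_days <= 0:
            raise ValueError("age_max_days must be > 0")
        lo, hi = self.df_search_range
        if lo < 0 or hi < lo:
            raise ValueError("df_search_range must be non-negative and ordered")
        p = list(self.percentiles)
        if any(not 0 < v < 100 for v in p) or any(b <= a for a, b in zip(p, p[1:])):
            raise ValueError("percentiles must be strictly increasing in (0, 100)")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        for key in ("df_search_range", "percentiles", "weight_window", "height_window"):
            if key in payload:
                payload[key] = tuple(payload[key])
        return cls(**payload)

    def to_yaml(self, path) -> None:
        payload = {k: (list(v) if isinstance(v, tuple) else v) for k, v in self.__dict__.items()}
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh)


def read_children_table(path, vmap: VariableMap | None = None) -> pd.DataFrame:
    """Read a child table CSV, renaming source columns to canonical fields.

    Unmapped columns are preserved as pass-through metadata; row order is
    preserved.  Rows with unparsable numeric cells are flagged via the
    ``invalid`` / ``invalid_reason`` columns rather than dropped.  DK
    sentinel codes (8/9) in binary survey items become missing.
    """
    vmap = vmap or VariableMap()
    raw = pd.read_csv(path, dtype=str, keep_default_na=True, skipinitialspace=True)
    # a column already under its canonical name needs no mapping
    missing = [
        src
        for canon, src in vmap.mapping.items()
        if src not in raw.columns and canon not in raw.columns
    ]
    if missing:
        raise KeyError(f"mapped column(s) absent from {path}: {sorted(missing)}")
    rename = {src: canon for canon, src in vmap.mapping.items() if src in raw.columns}
    df = raw.rename(columns=rename)

    invalid_reason = pd.Series("", index=df.index)
    for col in NUMERIC_FIELDS:
        if col not in df.columns:
            continue
        text = df[col].astype("string")
        num = pd.to_numeric(text, errors="coerce").astype(float)
        bad = np.isnan(num) & text.notna() & (text.str.strip() != "")
        if bad.any():
            invalid_reason[bad] = (invalid_reason[bad] + f" {col}").str.strip()
        df[col] = num
    for col in BINARY_FIELDS:
        if col in df.columns:
            df.loc[df[col].isin(DK_SENTINELS), col] = np.nan
    for col in ("singleton", "full_term", "mother_smokes"):
        if col in df.columns:
            df[col] = (
                df[col]
                .map(lambda v: {"true": True, "false": False, "1": True, "0": False}.get(str(v).strip().lower(), np.nan))
                .astype(object)
            )
    # pass-through columns keep their text form unless fully numeric
    canonical = set(NUMERIC_FIELDS) | {"singleton", "full_term", "mother_smokes"}
    for col in df.columns:
        if col in canonical or not pd.api.types.is_object_dtype(df[col]) and not pd.api.types.is_string_dtype(df[col]):
            continue
        converted = pd.to_numeric(df[col], errors="coerce")
        if converted.notna().equals(df[col].notna()):
            df[col] = converted
    if "age_days" in df.columns:
        df["age_days"] = df["age_days"].round().astype("Int64")
    df["invalid"] = invalid_reason != ""
    df["invalid_reason"] = invalid_reason
    return df


def write_children_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


@dataclass
class WHOReference:
    """External reference chart: one row per age, one column per percentile."""

    measure: str
    sex: str
    table: pd.DataFrame  # columns: age_days + percentile labels

    @property
    def ages(self) -> np.ndarray:
        return self.table["age_days"].to_numpy()

    @property
    def percentile_labels(self) -> list:
        return [c for c in self.table.columns if c != "age_days"]


def read_who_reference(path, measure: str = "weight", sex: str = "male") -> WHOReference:
    """Read a reference-percentile CSV (age-in-days column + one column
    per percentile label); ages sorted ascending, duplicates rejected,
    non-monotone percentile rows warned about."""
    df = pd.read_csv(path)
    if "age_days" not in df.columns:
        raise ValueError("reference table must have an 'age_days' column")
    if df["age_days"].duplicated().any():
        dup = sorted(df.loc[df["age_days"].duplicated(), "age_days"].unique().tolist())
        raise ValueError(f"duplicate age rows in reference table: {dup}")
    df = df.sort_values("age_days").reset_index(drop=True)
    pcols = [c for c in df.columns if c != "age_days"]
    vals = df[pcols].to_numpy(dtype=float)
    if np.any(np.diff(vals, axis=1) <= 0):
        warnings.warn("non-monotone percentile values in reference table", stacklevel=2)
    return WHOReference(measure=measure, sex=sex, table=df)


def write_centile_table(table, path) -> None:
    """Write a centile table as CSV: age, lambda, mu, sigma, tau, percentiles.

    Values round-trip exactly (shortest-repr float formatting)."""
    table.frame().to_csv(path, index=False)


def read_centile_table(path):
    from .charts import CentileTable

    df = pd.read_csv(path, float_precision="round_trip")
    required = ["age_days", "lambda", "mu", "sigma", "tau"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"centile table missing column(s) {missing}")
    return CentileTable.from_frame(df)


def week_of(age_days) -> np.ndarray:
    """Reporting convention: week = floor(days / 7)."""
    return np.asarray(age_days, dtype=int) // 7
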