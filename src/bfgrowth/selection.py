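"""Survey case selection for the growth-standards sample.

Implements the derivation algorithms for the three indicators that are
not directly available in a MICS-style child table, and the full
inclusion/exclusion chain:

* exclusive breastfeeding (EBF): still breastfed (Z = 1) and zero of
  the nine liquid items X = sum(x_i) and fifteen food items
  Y = sum(y_i) consumed in the last 24 hours, i.e. EBF = 1 iff
  Z = 1 and X + Y = 0;
* severe illness: diarrhea episode together with at least one of
  fever, cough, or breathing difficulty (L = 1 iff L1 = 1 and
  (L2 = 1 or L3 = 1 or L4 = 1));
* household congestion: adults per sleeping room
  C = (C1 - C2 - C3) / C4 with non-congested defined as C <= 2
  (the boundary C = 2.0 counts as non-congested).

Missingness is a value, not an error: under the default ``exclude``
policy a child with unknown feeding or illness items cannot be
certified, so the indicator is *undetermined* (NaN) and the record is
dropped by the chain.  ``treat_missing_as_zero`` is offered for
sensitivity analysis.

Included children are under six months (age <= 182 days by default),
singleton, full term, of birth order up to four, born to non-smoking
mothers, exclusively breastfed, without severe illness, and living in
non-congested households.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic import FOOD_COLS, LIQUID_COLS

MISSING_POLICIES = ("exclude", "treat_missing_as_zero")


@dataclass
class SelectionReport:
    """Counts removed at each stage of the inclusion/exclusion chain."""

    n_input: int
    stage_removed: dict = field(default_factory=dict)  # criterion -> n removed at that stage
    stage_remaining: dict = field(default_factory=dict)
    n_selected: int = 0
    by_sex: dict = field(default_factory=dict)
    by_province: dict = field(default_factory=dict)
    by_area: dict = field(default_factory=dict)
    order_invariant: bool = True
    selected_ids: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "stage_removed": dict(self.stage_removed),
            "stage_remaining": dict(self.stage_remaining),
            "n_selected": self.n_selected,
            "by_sex": dict(self.by_sex),
            "by_province": dict(self.by_province),
            "by_area": dict(self.by_area),
            "order_invariant": self.order_invariant,
        }


def ebf_status(records: pd.DataFrame, missing_policy: str = "exclude") -> pd.Series:
    """Exclusive-breastfeeding indicator: 1, 0, or NaN (undetermined)."""
    if missing_policy not in MISSING_POLICIES:
        raise ValueError(f"missing_policy must be one of {MISSING_POLICIES}")
    items = records[LIQUID_COLS + FOOD_COLS]
    Z = records["still_breastfed"]
    if missing_policy == "treat_missing_as_zero":
        items = items.fillna(0.0)
        Z = Z.fillna(0.0)
    XY = items.sum(axis=1, skipna=False)
    out = np.where((Z == 1) & (XY == 0), 1.0, 0.0)
    undetermined = Z.isna() | (XY.isna() & (Z == 1))
    out = pd.Series(out, index=records.index, name="ebf")
    out[undetermined] = np.nan
    return out


def severe_illness(records: pd.DataFrame) -> pd.Series:
    """Severe-illness indicator: 1, 0, or NaN (undetermined).

    Undetermined when diarrhea status is missing, or when diarrhea is
    present but all three companion symptoms are missing.
    """
    L1 = records["diarrhea"]
    comp = records[["fever", "cough", "breathing_difficulty"]]
    any_comp = (comp == 1).any(axis=1)
    all_comp_missing = comp.isna().all(axis=1)
    out = np.where((L1 == 1) & any_comp, 1.0, 0.0)
    out = pd.Series(out, index=records.index, name="severe_illness")
    out[L1.isna() | ((L1 == 1) & all_comp_missing & ~any_comp)] = np.nan
    return out


def adults_per_room(records: pd.DataFrame) -> pd.Series:
    """Adults per sleeping room C = (C1 - C2 - C3)/C4; NaN if undetermined."""
    C1 = records["hh_members"]
    C2 = records["under5"]
    C3 = records["age5_17"]
    C4 = records["sleeping_rooms"]
    adults = C1 - (C2 + C3)
    bad_rooms = C4.isna() | (C4 == 0)
    negative = adults < 0
    if negative.any():
        warnings.warn(
            f"{int(negative.sum())} record(s) with more children than household "
            "members; adults-per-room undetermined",
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        C = adults / C4
    C = pd.Series(np.asarray(C, dtype=float), index=records.index, name="adults_per_room")
    C[bad_rooms | negative] = np.nan
    return C


def _criterion_masks(records: pd.DataFrame, config) -> dict:
    """Boolean keep-masks per criterion (NaN / undetermined => False)."""
    ebf = ebf_status(records, config.missing_policy)
    ill = severe_illness(records)
    cong = adults_per_room(records)
    bo = pd.to_numeric(records["birth_order"], errors="coerce")
    return {
        "age": pd.to_numeric(records["age_days"], errors="coerce") <= config.age_max_days,
        "singleton": records["singleton"].astype("boolean").fillna(False).astype(bool),
        "full_term": records["full_term"].astype("boolean").fillna(False).astype(bool),
        "birth_order": bo.le(config.max_birth_order).fillna(False).astype(bool),
        "nonsmoking_mother": ~records["mother_smokes"].astype("boolean").fillna(True).astype(bool),
        "ebf": ebf.eq(1.0).fillna(False),
        "no_severe_illness": ill.eq(0.0).fillna(False),
        "non_congested": cong.le(config.max_adults_per_room).fillna(False),
    }


def select_children(records: pd.DataFrame, config) -> tuple[pd.DataFrame, SelectionReport]:
    """Apply the inclusion/exclusion chain; returns (selected, report).

    Criteria are applied in a fixed order for stage accounting, with an
    any-order audit confirming the final set is order-invariant (each
    criterion is a pure per-record predicate, so it must be).
    """
    masks = _criterion_masks(records, config)
    report = SelectionReport(n_input=len(records))
    keep = pd.Series(True, index=records.index)
    for name, mask in masks.items():
        new_keep = keep & mask
        report.stage_removed[name] = int(keep.sum() - new_keep.sum())
        report.stage_remaining[name] = int(new_keep.sum())
        keep = new_keep
    conj = pd.Series(True, index=records.index)
    for mask in reversed(list(masks.values())):
        conj &= mask
    report.order_invariant = bool(keep.equals(conj))
    selected = records.loc[keep].copy()
    report.n_selected = len(selected)
    report.selected_ids = selected["id"].tolist() if "id" in selected else selected.index.tolist()
    report.by_sex = selected["sex"].value_counts().to_dict() if "sex" in selected else {}
    report.by_province = selected["province"].value_counts().to_dict() if "province" in selected else {}
    report.by_area = selected["area"].value_counts().to_dict() if "area" in selected else {}
    return selected, report
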