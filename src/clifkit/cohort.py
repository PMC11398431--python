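"""ICU cohort discovery from ADT segments and consortium-style outlier handling.

The analysis population is the general adult ICU population: encounters
aged >= 18 at admission whose first ICU stay begins within 48 hours of
hospital admission and lasts at least 24 hours. This excludes patients
admitted to the ICU briefly for procedures and those arriving in the ICU
late in a hospitalization. ICU time is accounted as the contiguous block
from first ICU entry, merging back-to-back ICU segments separated by less
than an hour (transfer artifacts).

Outlier handling never deletes rows: values outside consortium-style
plausibility ranges (e.g. a heart rate of 1,000 beats per minute) are set
to missing and counted, preserving record counts and timestamps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .schema import ClifDataset, MissingColumnError

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Criteria
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortCriteria:
    """Inclusion thresholds; all boundaries are inclusive."""

    min_age_years: float = 18.0
    max_icu_entry_offset_hours: float = 48.0
    min_icu_stay_hours: float = 24.0
    window_start: str = "2020-01-01"
    window_end: str = "2021-12-31"
    #: ICU segments separated by less than this are one contiguous stay
    merge_gap_hours: float = 1.0

    def __post_init__(self) -> None:
        if min(self.min_age_years, self.max_icu_entry_offset_hours,
               self.min_icu_stay_hours) < 0:
            raise ValueError("criteria thresholds must be non-negative")
        if pd.Timestamp(self.window_start) > pd.Timestamp(self.window_end):
            raise ValueError("window start must not exceed window end")


def discover_icu_cohort(dataset: ClifDataset,
                        criteria: Optional[CohortCriteria] = None) -> pd.DataFrame:
    """Identify qualifying ICU encounters.

    An encounter qualifies iff age at admission >= ``min_age_years``, the
    first ICU ADT segment starts within ``max_icu_entry_offset_hours`` of
    the hospital admission datetime, the contiguous ICU time from that
    first entry is at least ``min_icu_stay_hours``, and the hospital
    admission date falls inside the window. Window membership is by
    admission date, not ICU entry.

    Returns one row per cohort member: identifiers, ICU entry/exit of the
    first contiguous ICU block, age, demographics, and the
    ``in_hospital_death`` / ``ever_imv`` outcome flags. Encounters without
    any ADT rows are skipped with a logged warning.
    """
    criteria = criteria or CohortCriteria()
    for required in ("adt", "hospitalization", "patient"):
        if required not in dataset.tables:
            raise MissingColumnError(f"dataset lacks the {required!r} table")

    hosp = dataset["hospitalization"]
    adt = dataset["adt"]

    missing_adt = set(hosp["hospitalization_id"]) - set(adt["hospitalization_id"])
    if missing_adt:
        logger.warning("skipping %d encounter(s) without ADT rows", len(missing_adt))

    icu = adt[adt["location_category"].astype(str).str.lower() == "icu"]
    icu = icu.sort_values(["hospitalization_id", "in_dttm"], kind="mergesort")

    gap = pd.Timedelta(hours=criteria.merge_gap_hours)
    first_blocks = {}
    for hid, grp in icu.groupby("hospitalization_id", sort=False):
        start = grp["in_dttm"].iloc[0]
        end = grp["out_dttm"].iloc[0]
        for in_t, out_t in zip(grp["in_dttm"].iloc[1:], grp["out_dttm"].iloc[1:]):
            if in_t - end < gap:      # contiguous with the first block
                end = max(end, out_t)
            else:
                break                 # later, separate ICU visits don't count
        first_blocks[hid] = (start, end)
    if not first_blocks:
        blocks = pd.DataFrame(columns=["hospitalization_id", "icu_entry_dttm",
                                       "icu_exit_dttm"])
    else:
        blocks = pd.DataFrame(
            [(hid, s, e) for hid, (s, e) in first_blocks.items()],
            columns=["hospitalization_id", "icu_entry_dttm", "icu_exit_dttm"])

    members = hosp.merge(blocks, on="hospitalization_id", how="inner")
    members = members.merge(dataset["patient"], on="patient_id", how="left")

    offset_h = (members["icu_entry_dttm"] - members["admission_dttm"]) \
        / pd.Timedelta(hours=1)
    stay_h = (members["icu_exit_dttm"] - members["icu_entry_dttm"]) \
        / pd.Timedelta(hours=1)
    age = pd.to_numeric(members["age_at_admission"], errors="coerce")
    adm_date = members["admission_dttm"].dt.tz_convert("UTC").dt.date
    w_start = pd.Timestamp(criteria.window_start).date()
    w_end = pd.Timestamp(criteria.window_end).date()

    keep = (
        (age >= criteria.min_age_years)
        & (offset_h >= 0)
        & (offset_h <= criteria.max_icu_entry_offset_hours)
        & (stay_h >= criteria.min_icu_stay_hours)
        & (adm_date >= w_start)
        & (adm_date <= w_end)
    )
    members = members[keep].copy()
    members["age_at_admission"] = age[keep]
    members["icu_entry_offset_h"] = offset_h[keep]
    members["icu_stay_h"] = stay_h[keep]
    members["in_hospital_death"] = (
        members["discharge_category"].astype(str).str.lower() == "expired")

    ever_imv = set()
    if "respiratory_support" in dataset.tables:
        rs = dataset["respiratory_support"]
        ever_imv = set(rs.loc[
            rs["device_category"].astype(str).str.lower() == "imv",
            "hospitalization_id"])
    members["ever_imv"] = members["hospitalization_id"].isin(ever_imv)

    columns = ["hospitalization_id", "patient_id", "icu_entry_dttm",
               "icu_exit_dttm", "age_at_admission", "icu_entry_offset_h",
               "icu_stay_h", "sex_category", "race_category",
               "ethnicity_category", "in_hospital_death", "ever_imv"]
    return members[columns].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Outlier ranges
# ---------------------------------------------------------------------------

def make_outlier_ranges(rows) -> pd.DataFrame:
    """Build an outlier-range table from (stream, category, min, max, unit)
    rows, checking min < max and (stream, category) uniqueness."""
    df = pd.DataFrame(rows, columns=["stream", "category", "min_plausible",
                                     "max_plausible", "unit"])
    if (df["min_plausible"] >= df["max_plausible"]).any():
        raise ValueError("min_plausible must be below max_plausible")
    if df.duplicated(["stream", "category"]).any():
        raise ValueError("one range per (stream, category)")
    return df


#: artifact defaults for common vitals/labs; fully overridable — the
#: consortium's own range table is site configuration, not published data
DEFAULT_OUTLIER_RANGES = make_outlier_ranges([
    ("vitals", "temp_c", 32.0, 44.0, "degC"),
    ("vitals", "temp_f", 89.6, 111.2, "degF"),
    ("vitals", "heart_rate", 20.0, 300.0, "bpm"),
    ("vitals", "sbp", 40.0, 300.0, "mmHg"),
    ("vitals", "dbp", 20.0, 200.0, "mmHg"),
    ("vitals", "map_mmhg", 30.0, 250.0, "mmHg"),
    ("vitals", "resp_rate", 2.0, 80.0, "breaths/min"),
    ("vitals", "spo2", 50.0, 100.0, "%"),
    ("vitals", "weight_kg", 20.0, 400.0, "kg"),
    ("vitals", "height_cm", 50.0, 250.0, "cm"),
    ("labs", "albumin", 1.0, 6.0, "g/dL"),
    ("labs", "ast", 0.0, 5000.0, "U/L"),
    ("labs", "alt", 0.0, 5000.0, "U/L"),
    ("labs", "hemoglobin", 2.0, 25.0, "g/dL"),
    ("labs", "creatinine", 0.1, 20.0, "mg/dL"),
    ("labs", "wbc", 0.0, 200.0, "10^3/uL"),
    ("labs", "lactate", 0.0, 30.0, "mmol/L"),
    ("labs", "sodium", 100.0, 185.0, "mEq/L"),
    ("labs", "potassium", 1.0, 12.0, "mEq/L"),
    ("labs", "bilirubin_total", 0.0, 60.0, "mg/dL"),
    ("labs", "platelet_count", 0.0, 2000.0, "10^3/uL"),
    ("labs", "glucose", 10.0, 2000.0, "mg/dL"),
])

_STREAM_COLUMNS = {
    "vitals": ("vital_category", "vital_value"),
    "labs": ("lab_category", "lab_value"),
}


def apply_outlier_ranges(dataset: ClifDataset,
                         ranges: Optional[pd.DataFrame] = None):
    """Set implausible numeric values to missing; never delete rows.

    Returns ``(cleaned dataset, removal report)`` where the report counts
    removals per (stream, category). Values exactly at a bound are kept;
    the operation is idempotent.
    """
    ranges = DEFAULT_OUTLIER_RANGES if ranges is None else ranges
    cleaned = dataset.copy()
    report_rows = []
    for stream, grp in ranges.groupby("stream", sort=True):
        if stream not in cleaned.tables:
            continue
        cat_col, value_col = _STREAM_COLUMNS[stream]
        df = cleaned.tables[stream]
        values = pd.to_numeric(df[value_col], errors="coerce")
        cats = df[cat_col].astype(str).str.lower()
        removed_any = np.zeros(len(df), dtype=bool)
        for _, row in grp.iterrows():
            in_cat = (cats == str(row["category"]).lower()).to_numpy()
            bad = in_cat & values.notna().to_numpy() & (
                (values < row["min_plausible"]) | (values > row["max_plausible"])
            ).to_numpy()
            n_bad = int(bad.sum())
            report_rows.append({"stream": stream, "category": row["category"],
                                "n_removed": n_bad})
            removed_any |= bad
        if removed_any.any():
            df = df.copy()
            col = df[value_col].to_numpy(dtype=float, copy=True)
            col[removed_any] = np.nan
            df[value_col] = col
            cleaned.tables[stream] = df
    report = pd.DataFrame(report_rows,
                          columns=["stream", "category", "n_removed"])
    return cleaned, report
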