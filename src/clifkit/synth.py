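"""Synthetic multi-site ICU data generator with known ground truth.

Real CLIF databases cannot be shared, so every downstream stage of the
package is exercised against synthetic encounters whose true subphenotype,
outcome probabilities, cohort eligibility and injected data-entry errors
are all recorded. The generator emulates the structure of a consortium
cohort: adult ICU encounters over a two-year window, ADT location
segments, hourly vitals, Poisson-thinned labs, respiratory-support rows,
and temperature curves built as a labelled reference trajectory plus
i.i.d. Gaussian noise.

Defaults mirror the consortium cohort where its characteristics are
reported (mean age 60.6 [SD 17.2], 45% female, ~9.5% hospital mortality,
~38% mechanical ventilation, race and ethnicity mix, 0.07% of encounters
without any recorded temperature). Subphenotype mixture weights take
midpoints of the reported per-site prevalence ranges, renormalised —
an arbitrary but fixed choice, flagged as such. All randomness flows from
a single seeded generator; the same config and seed reproduce the dataset
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import truncnorm

from .cohort import DEFAULT_OUTLIER_RANGES
from .schema import ClifDataset
from .trajectory import (
    ReferenceTrajectorySet,
    SUBPHENOTYPE_LABELS,
    WINDOW_HOURS,
)

# ---------------------------------------------------------------------------
# Reference trajectories
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrajectoryShape:
    """Exponential-approach temperature curve: ``plateau + (start - plateau)
    * 2**(-t / half_life_h)``. ``half_life_h=None`` gives a flat curve."""

    start: float
    plateau: float
    half_life_h: Optional[float] = None

    def curve(self, hours: np.ndarray) -> np.ndarray:
        hours = np.asarray(hours, dtype=float)
        if self.half_life_h is None or self.start == self.plateau:
            return np.full_like(hours, self.plateau)
        return self.plateau + (self.start - self.plateau) * np.exp2(-hours / self.half_life_h)


#: qualitative shapes implied by the subphenotype labels: NT flat at 37.0;
#: HT starting low and staying below NT; HFR febrile onset resolving within
#: ~a day; HSR febrile onset resolving slowly over ~three days.
DEFAULT_TRAJECTORY_SHAPES = {
    "NT": TrajectoryShape(37.0, 37.0, None),
    "HT": TrajectoryShape(36.2, 36.5, 36.0),
    "HFR": TrajectoryShape(38.6, 37.0, 6.0),
    "HSR": TrajectoryShape(38.6, 37.0, 30.0),
}


def default_reference_trajectories(shapes: Optional[dict] = None) -> ReferenceTrajectorySet:
    """Parameterised stand-in reference curves over hours 0..72.

    These are synthetic stand-ins with the qualitative shapes the
    subphenotype labels imply — they are NOT the published group-based
    trajectory model curves, which are not publicly printed. Externally
    supplied curves (``ReferenceTrajectorySet.from_csv``) drop in anywhere
    these are accepted.
    """
    shapes = shapes or DEFAULT_TRAJECTORY_SHAPES
    hours = np.arange(WINDOW_HOURS + 1, dtype=float)
    return ReferenceTrajectorySet(
        {label: shapes[label].curve(hours) for label in SUBPHENOTYPE_LABELS}
    )


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

class OutcomeModelConfig(BaseModel):
    """True logistic model for a binary outcome.

    The linear predictor is ``age_coef_per_year*(age-60) + subphenotype
    log-odds + albumin_coef*(albumin_latent-3.5)``; the intercept is solved
    numerically so the realised cohort's expected prevalence equals
    ``target_prevalence``, which keeps effect sizes and marginal rates
    independently configurable.
    """

    target_prevalence: float = Field(gt=0.0, lt=1.0)
    age_coef_per_year: float = 0.0
    coef_ht: float = 0.0
    coef_hfr: float = 0.0
    coef_hsr: float = 0.0
    albumin_coef: float = 0.0


class SynthConfig(BaseModel):
    """Study conditions for one synthetic site."""

    n_encounters: int = Field(default=500, gt=0)
    seed: int = Field(default=20240904, ge=0)
    site_label: str = "synthetic_site"
    n_hospitals: int = Field(default=3, gt=0)
    window_start: str = "2020-01-01"
    window_end: str = "2021-12-31"

    age_mean: float = 60.6
    age_sd: float = Field(default=17.2, gt=0.0)
    age_min: Optional[float] = 18.0     # truncation; None disables it
    female_frac: float = Field(default=0.45, ge=0.0, le=1.0)
    race_probs: dict = Field(default_factory=lambda: {
        "asian": 0.036, "black": 0.296, "white": 0.587, "other": 0.081})
    hispanic_frac: float = Field(default=0.071, ge=0.0, le=1.0)

    icu_entry_offset_mean_h: float = Field(default=12.0, gt=0.0)
    icu_los_median_h: float = Field(default=72.0, gt=0.0)
    icu_los_log_sd: float = Field(default=0.8, gt=0.0)
    post_icu_ward_mean_h: float = Field(default=48.0, ge=0.0)

    subphenotype_weights: dict = Field(default_factory=lambda: {
        "NT": 0.567, "HT": 0.240, "HFR": 0.072, "HSR": 0.121})

    temp_noise_sd: float = Field(default=0.3, gt=0.0)
    temp_obs_prob: float = Field(default=1.0, gt=0.0, le=1.0)
    zero_temp_frac: float = Field(default=0.0007, ge=0.0, le=1.0)
    temp_f_frac: float = Field(default=0.3, ge=0.0, le=1.0)

    vitals_streams: tuple = ("temp", "heart_rate", "sbp", "dbp", "resp_rate", "spo2")
    lab_streams: tuple = ("albumin", "ast", "hemoglobin", "creatinine",
                          "wbc", "lactate", "sodium", "potassium")
    lab_rate_per_day: float = Field(default=1.5, ge=0.0)
    vitals_max_days: float = Field(default=14.0, gt=0.0)

    outlier_rate: float = Field(default=0.001, ge=0.0, le=1.0)

    mortality: OutcomeModelConfig = Field(default_factory=lambda: OutcomeModelConfig(
        target_prevalence=0.095, age_coef_per_year=0.03,
        coef_ht=float(np.log(2.0)), coef_hfr=float(np.log(1.6)),
        coef_hsr=float(np.log(2.0)), albumin_coef=-0.4))
    ventilation: OutcomeModelConfig = Field(default_factory=lambda: OutcomeModelConfig(
        target_prevalence=0.38, coef_ht=float(np.log(0.9)),
        coef_hfr=float(np.log(2.5)), coef_hsr=float(np.log(4.0))))

    @model_validator(mode="after")
    def _check(self) -> "SynthConfig":
        if set(self.subphenotype_weights) != set(SUBPHENOTYPE_LABELS):
            raise ValueError(f"subphenotype_weights needs keys {SUBPHENOTYPE_LABELS}")
        total = sum(self.subphenotype_weights.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"subphenotype weights sum to {total}, expected 1")
        if any(w < 0 for w in self.subphenotype_weights.values()):
            raise ValueError("subphenotype weights must be non-negative")
        if abs(sum(self.race_probs.values()) - 1.0) > 1e-6:
            raise ValueError("race probabilities must sum to 1")
        if pd.Timestamp(self.window_start) > pd.Timestamp(self.window_end):
            raise ValueError("window_start must not exceed window_end")
        return self

    @classmethod
    def from_file(cls, path) -> "SynthConfig":
        import json

        import yaml
        text = Path(path).read_text()
        payload = yaml.safe_load(text) if str(path).endswith((".yml", ".yaml")) \
            else json.loads(text)
        return cls(**payload)


@dataclass
class GroundTruth:
    """Per-encounter truth plus injected-outlier bookkeeping.

    ``encounters`` has one row per generated encounter: subphenotype label,
    outcome probabilities and realised outcomes, temperature availability,
    and cohort-eligibility flags. ``outliers`` locates every injected
    data-entry error as (table, positional row, category).
    """

    encounters: pd.DataFrame
    outliers: pd.DataFrame

    def write(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.encounters.to_csv(directory / "ground_truth_encounters.csv", index=False)
        self.outliers.to_csv(directory / "ground_truth_outliers.csv", index=False)


# ---------------------------------------------------------------------------
# Stream value models
# ---------------------------------------------------------------------------

# vitals (other than temperature): mean, sd, clip-low, clip-high — clip bounds
# sit strictly inside the default plausibility ranges so that, without
# injection, cleaning removes nothing
_VITAL_SPECS = {
    "heart_rate": ("PULSE", 85.0, 12.0, 40.0, 180.0),
    "sbp": ("BP SYSTOLIC", 120.0, 20.0, 60.0, 230.0),
    "dbp": ("BP DIASTOLIC", 68.0, 12.0, 35.0, 140.0),
    "resp_rate": ("RESPIRATIONS", 19.0, 4.0, 6.0, 55.0),
    "spo2": ("PULSE OXIMETRY", 96.0, 2.0, 70.0, 100.0),
}

# labs: raw-name, kind ("normal"/"lognormal"), p1, p2, clip-low, clip-high
_LAB_SPECS = {
    "albumin": ("ALBUMIN", "latent", 0.0, 0.2, 1.0, 6.0),
    "ast": ("AST (SGOT)", "lognormal", np.log(40.0), 0.8, 5.0, 4000.0),
    "hemoglobin": ("UCM_LAB HEMOGLOBIN - AUTOMATED", "normal", 11.0, 2.0, 3.0, 20.0),
    "creatinine": ("CREATININE", "lognormal", 0.0, 0.5, 0.2, 15.0),
    "wbc": ("WBC COUNT", "lognormal", np.log(10.0), 0.4, 0.5, 100.0),
    "lactate": ("LACTATE", "lognormal", np.log(1.8), 0.5, 0.2, 25.0),
    "sodium": ("SODIUM", "normal", 138.0, 5.0, 112.0, 168.0),
    "potassium": ("POTASSIUM", "normal", 4.1, 0.6, 1.6, 8.8),
}

_DISCHARGE_ALIVE = ("home", "snf", "hospice", "acute_rehab", "ltach", "other")
_DISCHARGE_ALIVE_P = (0.62, 0.18, 0.05, 0.08, 0.03, 0.04)


def _ragged_index(counts: np.ndarray):
    """For per-encounter row counts, return (encounter index, within-encounter
    position) arrays for a flat ragged layout."""
    counts = np.asarray(counts, dtype=np.int64)
    total = int(counts.sum())
    enc = np.repeat(np.arange(len(counts)), counts)
    offsets = np.cumsum(counts) - counts
    pos = np.arange(total) - np.repeat(offsets, counts)
    return enc, pos


def _solve_intercept(lp: np.ndarray, target: float) -> float:
    """Intercept b0 with mean(expit(b0 + lp)) == target on the realised cohort."""
    return float(brentq(lambda b0: expit(b0 + lp).mean() - target, -30.0, 30.0,
                        xtol=1e-10))


def _linear_predictor(model: OutcomeModelConfig, age, label_idx, albumin):
    coefs = np.array([0.0, model.coef_ht, model.coef_hfr, model.coef_hsr])
    return (model.age_coef_per_year * (age - 60.0)
            + coefs[label_idx]
            + model.albumin_coef * (albumin - 3.5))


# ---------------------------------------------------------------------------
# Generator
# ---------------------------------------------------------------------------

def generate_dataset(config: SynthConfig,
                     refset: Optional[ReferenceTrajectorySet] = None):
    """Generate one site's CLIF tables plus ground truth.

    Returns ``(ClifDataset, GroundTruth)``. The dataset passes
    :func:`clifkit.schema.validate_dataset` with zero violations; injected
    outliers change numeric values only (categories stay permissible) and
    are fully logged.
    """
    refset = refset or default_reference_trajectories()
    rng = np.random.default_rng(config.seed)
    n = config.n_encounters

    hosp_ids = np.array([f"H{i:06d}" for i in range(1, n + 1)], dtype=object)
    pat_ids = np.array([f"P{i:06d}" for i in range(1, n + 1)], dtype=object)

    start = pd.Timestamp(config.window_start, tz="UTC")
    end = pd.Timestamp(config.window_end, tz="UTC") + pd.Timedelta(days=1)
    total_min = int((end - start) / pd.Timedelta(minutes=1)) - 1
    admission = start + pd.to_timedelta(rng.integers(0, total_min, n), unit="m")

    if config.age_min is not None:
        a = (config.age_min - config.age_mean) / config.age_sd
        age = truncnorm.rvs(a, np.inf, loc=config.age_mean, scale=config.age_sd,
                            size=n, random_state=rng)
    else:
        age = rng.normal(config.age_mean, config.age_sd, n)
    age = np.round(np.maximum(age, 0.0), 1)

    sex = np.where(rng.random(n) < config.female_frac, "female", "male")
    race_levels = sorted(config.race_probs)
    race_p = np.array([config.race_probs[k] for k in race_levels], dtype=float)
    race = rng.choice(race_levels, size=n, p=race_p / race_p.sum())
    ethnicity = np.where(rng.random(n) < config.hispanic_frac,
                         "hispanic", "non_hispanic")

    offset_min = np.floor(rng.exponential(config.icu_entry_offset_mean_h, n) * 60
                          ).astype(np.int64)
    icu_entry = admission + pd.to_timedelta(offset_min, unit="m")
    los_h = rng.lognormal(np.log(config.icu_los_median_h), config.icu_los_log_sd, n)
    los_min = np.maximum(60, np.floor(los_h * 60).astype(np.int64))
    icu_exit = icu_entry + pd.to_timedelta(los_min, unit="m")
    entry_offset_h = offset_min / 60.0
    icu_stay_h = los_min / 60.0

    weights = np.array([config.subphenotype_weights[k] for k in SUBPHENOTYPE_LABELS])
    label_idx = rng.choice(len(SUBPHENOTYPE_LABELS), size=n, p=weights / weights.sum())
    labels = np.array(SUBPHENOTYPE_LABELS, dtype=object)[label_idx]

    albumin_latent = np.clip(rng.normal(3.5, 0.4, n), 1.5, 5.5)

    lp_mort = _linear_predictor(config.mortality, age, label_idx, albumin_latent)
    p_mort = expit(_solve_intercept(lp_mort, config.mortality.target_prevalence)
                   + lp_mort)
    death = rng.random(n) < p_mort

    lp_imv = _linear_predictor(config.ventilation, age, label_idx, albumin_latent)
    p_imv = expit(_solve_intercept(lp_imv, config.ventilation.target_prevalence)
                  + lp_imv)
    imv = rng.random(n) < p_imv

    ward_min = np.floor(rng.exponential(config.post_icu_ward_mean_h, n) * 60
                        ).astype(np.int64)
    discharge = icu_exit + pd.to_timedelta(np.where(death, 0, ward_min), unit="m")
    discharge_cat = np.where(
        death, "expired",
        rng.choice(_DISCHARGE_ALIVE, size=n, p=_DISCHARGE_ALIVE_P))

    zero_temp = rng.random(n) < config.zero_temp_frac
    hospital = rng.choice(
        np.array([f"{config.site_label}_hosp{j + 1}" for j in range(config.n_hospitals)],
                 dtype=object), size=n)

    # -- cohort eligibility bookkeeping (inclusive boundaries) -----------
    adm_date = admission.normalize()
    fail_age = age < 18.0
    fail_entry = entry_offset_h > 48.0
    fail_stay = icu_stay_h < 24.0
    fail_window = (adm_date < start.normalize()) | (adm_date > pd.Timestamp(
        config.window_end, tz="UTC").normalize())
    qualifies = ~(fail_age | fail_entry | fail_stay | fail_window)

    # -- core tables -----------------------------------------------------
    patient = pd.DataFrame({
        "patient_id": pat_ids,
        "sex_name": pd.Series(sex, dtype=object).str.capitalize(),
        "sex_category": pd.Series(sex, dtype=object),
        "race_name": pd.Series(race, dtype=object).str.capitalize(),
        "race_category": pd.Series(race, dtype=object),
        "ethnicity_name": pd.Series(ethnicity, dtype=object).str.replace("_", " ").str.title(),
        "ethnicity_category": pd.Series(ethnicity, dtype=object),
    })
    hospitalization = pd.DataFrame({
        "hospitalization_id": hosp_ids,
        "patient_id": pat_ids,
        "admission_dttm": admission,
        "discharge_dttm": discharge,
        "age_at_admission": age,
        "discharge_name": pd.Series(discharge_cat, dtype=object).str.replace("_", " ").str.title(),
        "discharge_category": pd.Series(discharge_cat, dtype=object),
    })

    adt_frames = []
    pre = icu_entry > admission
    if pre.any():
        adt_frames.append(pd.DataFrame({
            "hospitalization_id": hosp_ids[pre],
            "hospital_id": hospital[pre],
            "in_dttm": admission[pre],
            "out_dttm": icu_entry[pre],
            "location_name": np.where(entry_offset_h[pre] <= 6.0,
                                      "EMERGENCY DEPT", "MED SURG WARD"),
            "location_category": np.where(entry_offset_h[pre] <= 6.0, "ed", "ward"),
        }))
    adt_frames.append(pd.DataFrame({
        "hospitalization_id": hosp_ids,
        "hospital_id": hospital,
        "in_dttm": icu_entry,
        "out_dttm": icu_exit,
        "location_name": "INTENSIVE CARE",
        "location_category": "icu",
    }))
    post = (~death) & (discharge > icu_exit)
    if post.any():
        adt_frames.append(pd.DataFrame({
            "hospitalization_id": hosp_ids[post],
            "hospital_id": hospital[post],
            "in_dttm": icu_exit[post],
            "out_dttm": discharge[post],
            "location_name": "MED SURG WARD",
            "location_category": "ward",
        }))
    adt = pd.concat(adt_frames, ignore_index=True).sort_values(
        ["hospitalization_id", "in_dttm"], kind="mergesort").reset_index(drop=True)
    adt["location_name"] = adt["location_name"].astype(object)
    adt["location_category"] = adt["location_category"].astype(object)

    vitals = _build_vitals(config, rng, refset, hosp_ids, icu_entry, icu_stay_h,
                           label_idx, zero_temp)
    labs = _build_labs(config, rng, hosp_ids, icu_entry, icu_stay_h, albumin_latent)
    resp = _build_respiratory_support(config, rng, hosp_ids, icu_entry,
                                      icu_stay_h, imv)
    meds = _build_medications(rng, hosp_ids, icu_entry, imv)
    scores = _build_scores(config, rng, hosp_ids, icu_entry, icu_stay_h)

    # -- outlier injection (numeric values only) -------------------------
    outlier_records = []
    vitals = _inject_outliers(vitals, "vitals", "vital_category", "vital_value",
                              rng, config.outlier_rate, outlier_records)
    labs = _inject_outliers(labs, "labs", "lab_category", "lab_value",
                            rng, config.outlier_rate, outlier_records)
    outliers = pd.DataFrame(
        outlier_records,
        columns=["table", "row", "category", "injected_value", "original_value"])

    dataset = ClifDataset(
        tables={
            "patient": patient,
            "hospitalization": hospitalization,
            "adt": adt,
            "vitals": vitals,
            "labs": labs,
            "respiratory_support": resp,
            "medication_admin_continuous": meds,
            "scores": scores,
        },
        site_label=config.site_label,
    )

    encounters = pd.DataFrame({
        "hospitalization_id": hosp_ids,
        "patient_id": pat_ids,
        "age": age,
        "sex_category": sex,
        "race_category": race,
        "ethnicity_category": ethnicity,
        "subphenotype": labels,
        "mortality_prob": p_mort,
        "death": death,
        "ventilation_prob": p_imv,
        "imv": imv,
        "albumin_latent": albumin_latent,
        "zero_temp": zero_temp,
        "admission_dttm": admission,
        "icu_entry_dttm": icu_entry,
        "icu_exit_dttm": icu_exit,
        "entry_offset_h": entry_offset_h,
        "icu_stay_h": icu_stay_h,
        "fail_age": fail_age,
        "fail_entry_offset": fail_entry,
        "fail_stay": fail_stay,
        "fail_window": fail_window,
        "qualifies": qualifies,
    })
    return dataset, GroundTruth(encounters=encounters, outliers=outliers)


# -- stream builders ---------------------------------------------------------

def _build_vitals(config, rng, refset, hosp_ids, icu_entry, icu_stay_h,
                  label_idx, zero_temp) -> pd.DataFrame:
    frames = []
    cap_h = config.vitals_max_days * 24.0

    if "temp" in config.vitals_streams:
        n_hours = np.minimum(WINDOW_HOURS, np.floor(icu_stay_h)).astype(np.int64) + 1
        n_hours = np.where(zero_temp, 0, n_hours)
        enc, hours = _ragged_index(n_hours)
        keep = rng.random(len(enc)) < config.temp_obs_prob
        ref = refset.as_matrix()
        temp_c = (ref[label_idx[enc], hours]
                  + rng.normal(0.0, config.temp_noise_sd, len(enc)))
        as_f = rng.random(len(enc)) < config.temp_f_frac
        value = np.where(as_f, temp_c * 9.0 / 5.0 + 32.0, temp_c)
        frames.append(pd.DataFrame({
            "hospitalization_id": hosp_ids[enc],
            "recorded_dttm": icu_entry[enc] + pd.to_timedelta(hours, unit="h"),
            "vital_name": np.where(as_f, "TEMPERATURE FAHRENHEIT",
                                   "TEMPERATURE CELSIUS"),
            "vital_category": np.where(as_f, "temp_f", "temp_c"),
            "vital_value": value,
        })[keep])

    for stream in config.vitals_streams:
        if stream not in _VITAL_SPECS:
            continue
        raw_name, mean, sd, lo, hi = _VITAL_SPECS[stream]
        n_hours = np.minimum(cap_h, np.floor(icu_stay_h)).astype(np.int64) + 1
        enc, hours = _ragged_index(n_hours)
        shift = 0.0
        if stream == "heart_rate":
            # febrile subphenotypes run tachycardic
            shift = np.where(np.isin(label_idx[enc], (2, 3)), 8.0, 0.0)
        value = np.clip(rng.normal(mean, sd, len(enc)) + shift, lo, hi)
        frames.append(pd.DataFrame({
            "hospitalization_id": hosp_ids[enc],
            "recorded_dttm": icu_entry[enc] + pd.to_timedelta(hours, unit="h"),
            "vital_name": raw_name,
            "vital_category": stream,
            "vital_value": value,
        }))

    if not frames:
        return pd.DataFrame({
            "hospitalization_id": pd.Series(dtype=object),
            "recorded_dttm": pd.Series(dtype="datetime64[ns, UTC]"),
            "vital_name": pd.Series(dtype=object),
            "vital_category": pd.Series(dtype=object),
            "vital_value": pd.Series(dtype=float),
        })
    out = pd.concat(frames, ignore_index=True).sort_values(
        ["hospitalization_id", "recorded_dttm", "vital_category"],
        kind="mergesort").reset_index(drop=True)
    out["vital_name"] = out["vital_name"].astype(object)
    out["vital_category"] = out["vital_category"].astype(object)
    return out


def _build_labs(config, rng, hosp_ids, icu_entry, icu_stay_h, albumin_latent
                ) -> pd.DataFrame:
    frames = []
    for stream in config.lab_streams:
        raw_name, kind, p1, p2, lo, hi = _LAB_SPECS[stream]
        counts = rng.poisson(config.lab_rate_per_day * icu_stay_h / 24.0)
        enc, _ = _ragged_index(counts)
        t_min = np.floor(rng.uniform(0.0, np.maximum(icu_stay_h[enc], 1e-9)) * 60
                         ).astype(np.int64)
        if kind == "latent":       # observation noise around a per-encounter level
            value = albumin_latent[enc] + rng.normal(p1, p2, len(enc))
        elif kind == "lognormal":
            value = rng.lognormal(p1, p2, len(enc))
        else:
            value = rng.normal(p1, p2, len(enc))
        frames.append(pd.DataFrame({
            "hospitalization_id": hosp_ids[enc],
            "lab_result_dttm": icu_entry[enc] + pd.to_timedelta(t_min, unit="m"),
            "lab_name": raw_name,
            "lab_category": stream,
            "lab_value": np.clip(value, lo, hi),
        }))
    if not frames:
        return pd.DataFrame({
            "hospitalization_id": pd.Series(dtype=object),
            "lab_result_dttm": pd.Series(dtype="datetime64[ns, UTC]"),
            "lab_name": pd.Series(dtype=object),
            "lab_category": pd.Series(dtype=object),
            "lab_value": pd.Series(dtype=float),
        })
    out = pd.concat(frames, ignore_index=True).sort_values(
        ["hospitalization_id", "lab_result_dttm", "lab_category"],
        kind="mergesort").reset_index(drop=True)
    out["lab_name"] = out["lab_name"].astype(object)
    out["lab_category"] = out["lab_category"].astype(object)
    return out


def _build_respiratory_support(config, rng, hosp_ids, icu_entry, icu_stay_h,
                               imv) -> pd.DataFrame:
    frames = []
    idx_imv = np.flatnonzero(imv)
    if idx_imv.size:
        vent_h = np.maximum(6.0, 0.6 * icu_stay_h[idx_imv])
        counts = np.minimum(np.floor(vent_h / 6.0).astype(np.int64) + 1, 40)
        enc, pos = _ragged_index(counts)
        frames.append(pd.DataFrame({
            "hospitalization_id": hosp_ids[idx_imv][enc],
            "recorded_dttm": icu_entry[idx_imv][enc]
            + pd.to_timedelta(pos * 6, unit="h"),
            "device_name": "VENTILATOR",
            "device_category": "imv",
            "mode_name": "AC/VC",
            "mode_category": "assist_control_volume",
            "fio2_set": np.round(rng.uniform(0.3, 1.0, len(enc)), 2),
        }))
    idx_no = np.flatnonzero(~imv)
    if idx_no.size:
        frames.append(pd.DataFrame({
            "hospitalization_id": hosp_ids[idx_no],
            "recorded_dttm": icu_entry[idx_no] + pd.Timedelta(hours=1),
            "device_name": "NASAL CANNULA",
            "device_category": "nasal_cannula",
            "mode_name": None,
            "mode_category": None,
            "fio2_set": np.nan,
        }))
    out = pd.concat(frames, ignore_index=True).sort_values(
        ["hospitalization_id", "recorded_dttm"], kind="mergesort"
    ).reset_index(drop=True)
    for col in ("device_name", "device_category", "mode_name", "mode_category"):
        out[col] = out[col].astype(object)
    return out


def _build_medications(rng, hosp_ids, icu_entry, imv) -> pd.DataFrame:
    on_pressor = imv & (rng.random(len(imv)) < 0.4)
    idx = np.flatnonzero(on_pressor)
    counts = np.full(idx.size, 5, dtype=np.int64)
    enc, pos = _ragged_index(counts)
    out = pd.DataFrame({
        "hospitalization_id": hosp_ids[idx][enc] if idx.size else
        pd.Series(dtype=object),
        "admin_dttm": (icu_entry[idx][enc] + pd.to_timedelta(pos * 6, unit="h"))
        if idx.size else pd.Series(dtype="datetime64[ns, UTC]"),
        "med_name": "NOREPINEPHRINE 8MG/250ML",
        "med_category": "norepinephrine",
        "med_dose": np.round(rng.uniform(2.0, 20.0, len(enc)), 1) if idx.size
        else pd.Series(dtype=float),
        "med_dose_unit": "mcg/min",
    })
    out["med_name"] = out["med_name"].astype(object)
    out["med_category"] = out["med_category"].astype(object)
    out["med_dose_unit"] = out["med_dose_unit"].astype(object)
    return out.reset_index(drop=True)


def _build_scores(config, rng, hosp_ids, icu_entry, icu_stay_h) -> pd.DataFrame:
    n_days = np.minimum(np.ceil(icu_stay_h / 24.0).astype(np.int64),
                        int(config.vitals_max_days))
    enc, pos = _ragged_index(n_days)
    out = pd.DataFrame({
        "hospitalization_id": hosp_ids[enc],
        "recorded_dttm": icu_entry[enc] + pd.to_timedelta(pos * 24, unit="h"),
        "assessment_name": "GLASGOW COMA SCALE TOTAL",
        "assessment_category": "gcs_total",
        "numerical_value": np.clip(np.round(rng.normal(12.0, 3.0, len(enc))),
                                   3, 15),
    })
    out["assessment_name"] = out["assessment_name"].astype(object)
    out["assessment_category"] = out["assessment_category"].astype(object)
    return out.reset_index(drop=True)


def _inject_outliers(df, table, cat_col, value_col, rng, rate, records) -> pd.DataFrame:
    """Replace a random fraction of numeric values with values strictly above
    the plausible maximum for their category, logging every replacement."""
    if rate <= 0.0 or df.empty:
        return df
    ranges = DEFAULT_OUTLIER_RANGES.set_index("category")
    mask = rng.random(len(df)) < rate
    cats = df[cat_col].astype(str)
    mask &= cats.isin(ranges.index).to_numpy()
    positions = np.flatnonzero(mask)
    if positions.size == 0:
        return df
    df = df.copy()
    hi = ranges.loc[cats.iloc[positions], "max_plausible"].to_numpy(dtype=float)
    lo = ranges.loc[cats.iloc[positions], "min_plausible"].to_numpy(dtype=float)
    injected = hi + (hi - lo) * (0.5 + rng.random(positions.size))
    original = df[value_col].to_numpy(dtype=float)[positions]
    df.iloc[positions, df.columns.get_loc(value_col)] = injected
    for pos, cat, new, old in zip(positions, cats.iloc[positions], injected, original):
        records.append({"table": table, "row": int(pos), "category": str(cat),
                        "injected_value": float(new), "original_value": float(old)})
    return df
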