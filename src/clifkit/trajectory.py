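"""Temperature-trajectory subphenotyping over the first 72 ICU hours.

Body-temperature subphenotypes of critical illness — normothermic (NT),
hypothermic (HT), hyperthermic fast resolver (HFR) and hyperthermic slow
resolver (HSR) — were originally derived with group-based trajectory
modelling in infected inpatients. External validation does not re-fit that
model: each encounter's observed hourly temperatures are compared against
the four labelled reference trajectories and the encounter is assigned to
the subphenotype with the lowest mean squared error over its observed
hours. Encounters with no recorded temperature in the window are excluded.

Associations between subphenotype and ICU outcomes (in-hospital mortality,
invasive mechanical ventilation) are estimated with multivariable logistic
regression adjusted for age, sex, race and ethnicity, with NT as the
reference level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .schema import ClifDataset, ClifError

logger = logging.getLogger(__name__)

#: fixed subphenotype label order; also the tie-break order of the classifier
SUBPHENOTYPE_LABELS = ("NT", "HT", "HFR", "HSR")

#: analysis window in hours from ICU entry (inclusive of hour 72)
WINDOW_HOURS = 72

EXCLUSION_NO_TEMPERATURE = "no_temperature_measurements"


class FitFailureError(ClifError):
    """The outcome regression could not be fitted (e.g. perfect separation)."""


def fahrenheit_to_celsius(values):
    """C = (F - 32) * 5/9."""
    return (np.asarray(values, dtype=float) - 32.0) * 5.0 / 9.0


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class ReferenceTrajectorySet:
    """The four labelled hourly reference curves over hours 0..72 (deg C).

    ``curves`` maps each label in :data:`SUBPHENOTYPE_LABELS` to a complete
    length-73 array. Curves may come from :func:`clifkit.synth.
    default_reference_trajectories` or from an external CSV with columns
    ``hour, NT, HT, HFR, HSR``.
    """

    curves: dict

    def __post_init__(self) -> None:
        if set(self.curves) != set(SUBPHENOTYPE_LABELS):
            raise ValueError(f"curves must carry exactly the labels {SUBPHENOTYPE_LABELS}")
        for label, values in self.curves.items():
            arr = np.asarray(values, dtype=float)
            if arr.shape != (WINDOW_HOURS + 1,):
                raise ValueError(f"{label}: expected {WINDOW_HOURS + 1} hourly values")
            if np.isnan(arr).any():
                raise ValueError(f"{label}: reference curve has missing hours")
            self.curves[label] = arr

    def as_matrix(self) -> np.ndarray:
        """(4, 73) matrix in fixed label order."""
        return np.vstack([self.curves[k] for k in SUBPHENOTYPE_LABELS])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"hour": np.arange(WINDOW_HOURS + 1)})
        for k in SUBPHENOTYPE_LABELS:
            df[k] = self.curves[k]
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ReferenceTrajectorySet":
        df = pd.read_csv(path).sort_values("hour")
        return cls({k: df[k].to_numpy(dtype=float) for k in SUBPHENOTYPE_LABELS})


@dataclass
class TemperatureSeriesSet:
    """Hourly-binned temperatures for many encounters.

    ``values`` is indexed by hospitalization_id with integer columns 0..72;
    missing hours are NaN. ``exclusions`` lists encounters dropped for
    having no temperature measurement in the window.
    """

    values: pd.DataFrame
    exclusions: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["hospitalization_id", "reason"]))

    @property
    def n_observations(self) -> pd.Series:
        return self.values.notna().sum(axis=1)

    def __len__(self) -> int:
        return len(self.values)


# ---------------------------------------------------------------------------
# Series construction
# ---------------------------------------------------------------------------

def build_temperature_series(dataset: ClifDataset, cohort: pd.DataFrame,
                             window_hours: int = WINDOW_HOURS) -> TemperatureSeriesSet:
    """Standardize each cohort encounter's temperatures onto the hourly grid.

    Vitals rows with ``vital_category`` ``temp_c`` or ``temp_f`` (the latter
    converted to Celsius) whose timestamp lies within
    ``[icu_entry, icu_entry + window_hours]`` are binned to integer hours
    since ICU entry by within-hour mean. Encounters with zero temperature
    observations are excluded, with the reason recorded. Run outlier
    cleaning first so data-entry errors do not enter the bins.
    """
    vit = dataset["vitals"]
    cat = vit["vital_category"].astype(str).str.lower()
    temp = vit[cat.isin(("temp_c", "temp_f"))].copy()
    values = pd.to_numeric(temp["vital_value"], errors="coerce")
    is_f = cat.loc[temp.index] == "temp_f"
    temp["temp_c"] = np.where(is_f, fahrenheit_to_celsius(values), values)

    entry = cohort.set_index("hospitalization_id")["icu_entry_dttm"]
    temp = temp[temp["hospitalization_id"].isin(entry.index)]
    temp = temp.dropna(subset=["temp_c"])
    delta_h = (
        temp["recorded_dttm"] - temp["hospitalization_id"].map(entry)
    ) / pd.Timedelta(hours=1)
    temp = temp[(delta_h >= 0) & (delta_h <= window_hours)]
    temp["hour"] = np.floor(
        ((temp["recorded_dttm"] - temp["hospitalization_id"].map(entry))
         / pd.Timedelta(hours=1)).to_numpy()
    ).astype(int).clip(0, window_hours)

    binned = (
        temp.groupby(["hospitalization_id", "hour"])["temp_c"].mean().unstack("hour")
    )
    binned = binned.reindex(columns=range(window_hours + 1))
    binned.columns = [int(c) for c in binned.columns]

    all_ids = pd.Index(cohort["hospitalization_id"])
    observed_ids = binned.index[binned.notna().any(axis=1)]
    excluded_ids = all_ids.difference(observed_ids)
    exclusions = pd.DataFrame({
        "hospitalization_id": excluded_ids,
        "reason": EXCLUSION_NO_TEMPERATURE,
    })
    binned = binned.loc[binned.index.intersection(observed_ids)]
    # keep cohort order
    binned = binned.reindex(all_ids.intersection(binned.index))
    return TemperatureSeriesSet(values=binned, exclusions=exclusions)


def temperature_accounting(n_cohort: int, n_excluded: int) -> dict:
    """Analysis bookkeeping: encounters analyzed and percent excluded
    (two decimals), as reported alongside the subphenotype results."""
    if n_cohort <= 0:
        raise ValueError("cohort must be non-empty")
    return {
        "n_cohort": int(n_cohort),
        "n_excluded": int(n_excluded),
        "n_analyzed": int(n_cohort - n_excluded),
        "pct_excluded": round(100.0 * n_excluded / n_cohort, 2),
    }


# ---------------------------------------------------------------------------
# Minimum-MSE classification
# ---------------------------------------------------------------------------

def classify_subphenotype(series: TemperatureSeriesSet,
                          refset: ReferenceTrajectorySet) -> pd.DataFrame:
    """Assign each series to the reference trajectory with minimal MSE.

    For encounter ``i`` and subphenotype ``k`` the discrepancy is the mean
    over observed hours of ``(T_obs(h) - T_ref_k(h))**2``; the assigned
    label is the argmin, with ties broken in the fixed order NT < HT < HFR
    < HSR. Dividing by the observed-hour count makes sparse series
    comparable with dense ones. Raises for any series with zero observed
    hours — those must be excluded upstream.

    Returns a DataFrame with ``hospitalization_id``, ``mse_NT`` ...
    ``mse_HSR``, ``n_observations`` and ``assigned``.
    """
    obs = series.values.to_numpy(dtype=float)          # (n, 73)
    if obs.shape[0] and obs.shape[1] != WINDOW_HOURS + 1:
        raise ValueError("series grid must cover hours 0..72")
    mask = ~np.isnan(obs)
    n_obs = mask.sum(axis=1)
    if np.any(n_obs == 0):
        raise ValueError("series with zero observed hours; exclude upstream")

    refs = refset.as_matrix()                          # (4, 73)
    filled = np.where(mask, obs, 0.0)
    mse = np.empty((obs.shape[0], refs.shape[0]))
    for k in range(refs.shape[0]):
        sq = (filled - refs[k]) ** 2
        mse[:, k] = np.where(mask, sq, 0.0).sum(axis=1) / n_obs
    best = mse.argmin(axis=1)                          # first minimum wins

    out = pd.DataFrame({"hospitalization_id": series.values.index})
    for k, label in enumerate(SUBPHENOTYPE_LABELS):
        out[f"mse_{label}"] = mse[:, k]
    out["n_observations"] = n_obs
    out["assigned"] = [SUBPHENOTYPE_LABELS[b] for b in best]
    return out


# ---------------------------------------------------------------------------
# Adjusted outcome models
# ---------------------------------------------------------------------------

#: covariate -> (cohort column, reference level); None reference = continuous
ADJUSTMENT_COVARIATES = {
    "age": ("age_at_admission", None),
    "sex": ("sex_category", "female"),
    "race": ("race_category", "white"),
    "ethnicity": ("ethnicity_category", "non_hispanic"),
}

OUTCOME_COLUMNS = {"mortality": "in_hospital_death", "imv": "ever_imv"}


def _dummies(series: pd.Series, reference: str, prefix: str) -> pd.DataFrame:
    values = series.astype(str).str.lower()
    levels = [lv for lv in sorted(values.unique()) if lv != reference]
    return pd.DataFrame(
        {f"{prefix}[{lv}]": (values == lv).astype(float) for lv in levels},
        index=series.index,
    )


def adjusted_outcome_model(assignments: pd.DataFrame, cohort: pd.DataFrame,
                           outcome: str = "mortality",
                           covariates=("age", "sex", "race", "ethnicity"),
                           ) -> pd.DataFrame:
    """Logistic regression of an ICU outcome on subphenotype membership.

    Subphenotype enters as indicators with NT the reference level;
    adjustment covariates are age (continuous, years) and categorical sex,
    race and ethnicity. Fitting is iteratively reweighted least squares
    (binomial GLM) to gradient tolerance 1e-8. Returns an odds-ratio table
    with one row per model term: coefficient, SE, OR = exp(coef) and the
    Wald 95% CI exp(coef +/- 1.96 SE).

    Raises :class:`FitFailureError` on perfect separation or non-converged
    fits rather than returning silently unstable estimates.
    """
    if outcome not in OUTCOME_COLUMNS:
        raise ValueError(f"outcome must be one of {sorted(OUTCOME_COLUMNS)}")
    data = assignments[["hospitalization_id", "assigned"]].merge(
        cohort, on="hospitalization_id", how="inner")
    y = pd.to_numeric(data[OUTCOME_COLUMNS[outcome]], errors="coerce").astype(float)
    if y.nunique() < 2:
        raise FitFailureError("outcome has a single class")
    if not (data["assigned"] == "NT").any():
        raise FitFailureError("no NT encounters to serve as reference level")

    X = _dummies(data["assigned"], "nt", "subphenotype")
    for cov in covariates:
        column, reference = ADJUSTMENT_COVARIATES[cov]
        if reference is None:
            X[cov] = pd.to_numeric(data[column], errors="coerce")
        else:
            X = pd.concat([X, _dummies(data[column], reference, cov)], axis=1)
    X = sm.add_constant(X, has_constant="add")

    keep = y.notna() & X.notna().all(axis=1)
    y, X = y[keep], X[keep]
    try:
        fit = sm.GLM(y, X, family=sm.families.Binomial()).fit(tol=1e-8, maxiter=200)
    except PerfectSeparationError as exc:
        raise FitFailureError(f"perfect separation: {exc}") from exc
    if not fit.converged:
        raise FitFailureError("IRLS did not converge")
    if np.any(np.abs(fit.params.drop("const")) > 30):
        raise FitFailureError("diverged coefficients indicate separation")

    rows = []
    with np.errstate(over="ignore"):    # huge SEs at tiny n give inf CI bounds
        for term in X.columns:
            if term == "const":
                continue
            coef = float(fit.params[term])
            se = float(fit.bse[term])
            rows.append({
                "outcome": outcome,
                "term": term,
                "coefficient": coef,
                "se": se,
                "odds_ratio": float(np.exp(coef)),
                "ci_low": float(np.exp(coef - 1.96 * se)),
                "ci_high": float(np.exp(coef + 1.96 * se)),
            })
    return pd.DataFrame(rows)


def or_table_to_long(table: pd.DataFrame) -> pd.DataFrame:
    """Forest-plot-ready long format: one row per (outcome, term, statistic)."""
    return table.melt(
        id_vars=["outcome", "term"],
        value_vars=["odds_ratio", "ci_low", "ci_high", "coefficient", "se"],
        var_name="statistic", value_name="value",
    )
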