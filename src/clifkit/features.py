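"""First-24-hour feature extraction and the mortality-model harness.

Candidate predictors are simple aggregates (min / max / mean) of vitals and
labs over the half-open window [ICU entry, ICU entry + 24 h). Encounters
with no qualifying observation for a feature keep it missing — the model
family (gradient boosting with native missing-value routing) is chosen
precisely so that missingness needs no imputation. The default spec
implements the named headline predictors (minimum albumin, maximum and
mean AST, minimum pulse rate, minimum diastolic blood pressure) plus a
documented placeholder list of common vitals/labs aggregates; the exact
site list is configuration.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import lightgbm as lgb
import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .schema import ClifDataset, ConfigError, default_vocabularies
from .evaluation import auc

AGGREGATIONS = ("min", "max", "mean")

_STREAMS = {
    "vitals": ("vital_category", "vital_value", "recorded_dttm", "vital_category"),
    "labs": ("lab_category", "lab_value", "lab_result_dttm", "lab_category"),
}


@dataclass(frozen=True)
class FeatureItem:
    stream: str            # "vitals" | "labs"
    category: str
    aggregation: str       # min | max | mean
    name: str


@dataclass
class FeatureSpec:
    """Aggregation plan over the first-24-h window."""

    items: tuple
    window_hours: tuple = (0.0, 24.0)

    def __post_init__(self) -> None:
        names = [it.name for it in self.items]
        if len(names) != len(set(names)):
            raise ConfigError("feature output names must be unique")
        vocab = default_vocabularies()
        for it in self.items:
            if it.stream not in _STREAMS:
                raise ConfigError(f"unknown stream {it.stream!r}")
            if it.aggregation not in AGGREGATIONS:
                raise ConfigError(f"aggregation must be one of {AGGREGATIONS}")
            element = "vital_category" if it.stream == "vitals" else "lab_category"
            if not vocab[element].is_permitted(it.category):
                raise ConfigError(
                    f"{it.name}: category {it.category!r} is not a permitted "
                    f"{element} value")

    @property
    def names(self) -> tuple:
        return tuple(it.name for it in self.items)

    def to_json(self, path=None) -> str:
        payload = {
            "window_hours": list(self.window_hours),
            "items": [{"stream": it.stream, "category": it.category,
                       "aggregation": it.aggregation, "name": it.name}
                      for it in self.items],
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "FeatureSpec":
        from ._io import load_json_source
        payload = load_json_source(source)
        return cls(items=tuple(FeatureItem(**it) for it in payload["items"]),
                   window_hours=tuple(payload.get("window_hours", (0.0, 24.0))))


def default_feature_spec() -> FeatureSpec:
    """Headline predictors plus common vitals/labs aggregates (placeholders
    for a site's full a-priori predictor list)."""
    items = [
        FeatureItem("labs", "albumin", "min", "min_albumin"),
        FeatureItem("labs", "ast", "max", "max_ast"),
        FeatureItem("labs", "ast", "mean", "mean_ast"),
        FeatureItem("vitals", "heart_rate", "min", "min_pulse"),
        FeatureItem("vitals", "dbp", "min", "min_dbp"),
        # placeholder aggregates with expected low missingness
        FeatureItem("vitals", "heart_rate", "max", "max_pulse"),
        FeatureItem("vitals", "sbp", "min", "min_sbp"),
        FeatureItem("vitals", "resp_rate", "max", "max_resp_rate"),
        FeatureItem("vitals", "spo2", "min", "min_spo2"),
        FeatureItem("vitals", "temp_c", "min", "min_temp_c"),
        FeatureItem("vitals", "temp_c", "max", "max_temp_c"),
        FeatureItem("labs", "hemoglobin", "min", "min_hemoglobin"),
        FeatureItem("labs", "creatinine", "max", "max_creatinine"),
        FeatureItem("labs", "wbc", "max", "max_wbc"),
        FeatureItem("labs", "lactate", "max", "max_lactate"),
        FeatureItem("labs", "sodium", "min", "min_sodium"),
        FeatureItem("labs", "sodium", "max", "max_sodium"),
        FeatureItem("labs", "potassium", "max", "max_potassium"),
    ]
    return FeatureSpec(items=tuple(items))


def extract_features(dataset: ClifDataset, cohort: pd.DataFrame,
                     spec: Optional[FeatureSpec] = None) -> pd.DataFrame:
    """One row per cohort encounter; feature columns per the spec.

    Only observations with ``window_start <= t - icu_entry < window_end``
    (hours, half-open on the right) contribute. Encounters with no
    qualifying observation for a feature keep NaN — never imputed. The
    label column ``in_hospital_death`` is carried from the cohort. Output
    row order follows the cohort; input row order is irrelevant.
    """
    spec = spec or default_feature_spec()
    entry = cohort.set_index("hospitalization_id")["icu_entry_dttm"]
    lo, hi = spec.window_hours

    out = pd.DataFrame(index=pd.Index(cohort["hospitalization_id"],
                                      name="hospitalization_id"))
    for stream in ("vitals", "labs"):
        wanted = [it for it in spec.items if it.stream == stream]
        if not wanted or stream not in dataset.tables:
            continue
        cat_col, value_col, time_col, _ = _STREAMS[stream]
        df = dataset[stream]
        cats = {it.category for it in wanted}
        sub = df[df[cat_col].astype(str).str.lower().isin(cats)]
        sub = sub[sub["hospitalization_id"].isin(entry.index)]
        delta = (sub[time_col] - sub["hospitalization_id"].map(entry)) \
            / pd.Timedelta(hours=1)
        sub = sub[(delta >= lo) & (delta < hi)]
        values = pd.to_numeric(sub[value_col], errors="coerce")
        grouped = pd.DataFrame({
            "hospitalization_id": sub["hospitalization_id"],
            "category": sub[cat_col].astype(str).str.lower(),
            "value": values,
        }).dropna(subset=["value"]).groupby(["hospitalization_id", "category"])["value"]
        aggs = grouped.agg(["min", "max", "mean"])
        for it in wanted:
            try:
                col = aggs.xs(it.category, level="category")[it.aggregation]
            except KeyError:
                col = pd.Series(dtype=float)
            out[it.name] = out.index.map(col)
    for it in spec.items:
        if it.name not in out.columns:
            out[it.name] = np.nan
    out = out[list(spec.names)]

    labels = cohort.set_index("hospitalization_id")["in_hospital_death"]
    out["in_hospital_death"] = out.index.map(labels).astype(int)
    return out.reset_index()


# ---------------------------------------------------------------------------
# Model harness
# ---------------------------------------------------------------------------

DEFAULT_GRID = {
    "num_leaves": [7, 31],
    "learning_rate": [0.1],
    "n_estimators": [50, 150],
    "min_child_samples": [20],
}


@dataclass
class MortalityModel:
    """A trained gradient-boosting risk model plus its provenance."""

    booster: lgb.Booster
    feature_names: tuple
    params: dict
    cv_auc: float

    def save(self, path) -> None:
        """Portable text serialization (the backend's native TXT format)."""
        Path(path).write_text(self.booster.model_to_string())

    @classmethod
    def load(cls, path) -> "MortalityModel":
        booster = lgb.Booster(model_str=Path(path).read_text())
        return cls(booster=booster, feature_names=tuple(booster.feature_name()),
                   params={}, cv_auc=float("nan"))


def _lgb_params(point: dict, seed: int) -> dict:
    return dict(
        objective="binary", verbosity=-1, deterministic=True,
        force_row_wise=True, num_threads=1, seed=seed, **{
            k: v for k, v in point.items() if k != "n_estimators"},
    )


def train_mortality_model(features: pd.DataFrame,
                          grid: Optional[dict] = None,
                          k_folds: int = 5,
                          seed: int = 0) -> MortalityModel:
    """Grid search with stratified k-fold cross-validation by mean AUC.

    ``features`` is the output of :func:`extract_features` (label column
    ``in_hospital_death``). Missing values pass straight to the booster's
    native routing. Ties on CV AUC resolve to the first grid point in the
    deterministic iteration order (sorted keys, itertools product), so the
    chosen hyperparameters are reproducible for a fixed seed.
    """
    grid = grid or DEFAULT_GRID
    if not grid:
        raise ValueError("hyperparameter grid must be non-empty")
    X = features.drop(columns=["in_hospital_death", "hospitalization_id"],
                      errors="ignore")
    y = features["in_hospital_death"].to_numpy(dtype=int)
    if np.unique(y).size < 2:
        raise ValueError("labels contain a single class")

    keys = sorted(grid)
    points = [dict(zip(keys, combo)) for combo in
              itertools.product(*(grid[k] for k in keys))]
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(X, y))

    best_point, best_auc = None, -np.inf
    for point in points:
        fold_aucs = []
        for train_idx, test_idx in folds:
            train_set = lgb.Dataset(X.iloc[train_idx], label=y[train_idx])
            booster = lgb.train(_lgb_params(point, seed), train_set,
                                num_boost_round=point.get("n_estimators", 100))
            preds = booster.predict(X.iloc[test_idx])
            fold_aucs.append(auc(preds, y[test_idx]))
        mean_auc = float(np.mean(fold_aucs))
        if mean_auc > best_auc:
            best_point, best_auc = point, mean_auc

    final = lgb.train(_lgb_params(best_point, seed),
                      lgb.Dataset(X, label=y),
                      num_boost_round=best_point.get("n_estimators", 100))
    return MortalityModel(booster=final, feature_names=tuple(X.columns),
                          params=dict(best_point), cv_auc=best_auc)


def predict_risk(model: MortalityModel, features: pd.DataFrame) -> np.ndarray:
    """Per-encounter probability of in-hospital death.

    Columns are aligned to the training feature order; a missing feature
    column is a schema mismatch and raises :class:`ConfigError`. Rows with
    all features missing still get a valid probability.
    """
    missing = [c for c in model.feature_names if c not in features.columns]
    if missing:
        raise ConfigError(f"feature columns missing for this model: {missing}")
    X = features[list(model.feature_names)]
    probs = np.asarray(model.booster.predict(X), dtype=float)
    return np.clip(probs, 0.0, 1.0)
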