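"""Shared fixtures: seeded synthetic sites at the sizes the checks need."""

from types import SimpleNamespace

import numpy as np
import pandas as pd
import pytest

from clifkit import (
    SynthConfig,
    apply_outlier_ranges,
    discover_icu_cohort,
    generate_dataset,
    train_mortality_model,
)
from clifkit.synth import OutcomeModelConfig

#: base pandas timestamp helper used by handcrafted fixtures
T0 = pd.Timestamp("2020-06-01 00:00", tz="UTC")


def hours(h: float) -> pd.Timestamp:
    return T0 + pd.Timedelta(hours=h)


@pytest.fixture(scope="session")
def base_sim():
    """Default study conditions at desk scale, run through cleaning and
    cohort discovery once for the whole session."""
    config = SynthConfig(n_encounters=200, seed=101)
    dataset, truth = generate_dataset(config)
    cleaned, removals = apply_outlier_ranges(dataset)
    cohort = discover_icu_cohort(cleaned)
    return SimpleNamespace(config=config, dataset=dataset, truth=truth,
                           cleaned=cleaned, removals=removals, cohort=cohort)


def strong_signal_config(n: int, seed: int) -> SynthConfig:
    """Conditions for model-harness checks: outcome strongly driven by
    albumin and subphenotype so discrimination is learnable at desk scale."""
    return SynthConfig(
        n_encounters=n, seed=seed, outlier_rate=0.0, lab_rate_per_day=3.0,
        mortality=OutcomeModelConfig(
            target_prevalence=0.30, age_coef_per_year=0.0,
            coef_ht=float(np.log(3.0)), coef_hfr=float(np.log(2.0)),
            coef_hsr=float(np.log(4.0)), albumin_coef=-1.5),
    )


SMALL_GRID = {"num_leaves": [7], "learning_rate": [0.1],
              "n_estimators": [60], "min_child_samples": [20]}


@pytest.fixture(scope="session")
def trained_sim():
    """A strong-signal site with a fitted mortality model."""
    from clifkit import extract_features
    config = strong_signal_config(1200, seed=11)
    dataset, truth = generate_dataset(config)
    cohort = discover_icu_cohort(dataset)
    features = extract_features(dataset, cohort)
    model = train_mortality_model(features, grid=SMALL_GRID, seed=3)
    return SimpleNamespace(config=config, dataset=dataset, truth=truth,
                           cohort=cohort, features=features, model=model)
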