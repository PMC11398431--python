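"""Temperature standardization, min-MSE classification, adjusted models."""

import numpy as np
import pandas as pd
import pytest

from clifkit import (
    SynthConfig,
    adjusted_outcome_model,
    build_temperature_series,
    classify_subphenotype,
    default_reference_trajectories,
    discover_icu_cohort,
    fahrenheit_to_celsius,
    generate_dataset,
    temperature_accounting,
)
from clifkit.trajectory import (
    FitFailureError,
    ReferenceTrajectorySet,
    SUBPHENOTYPE_LABELS,
    TemperatureSeriesSet,
)

from conftest import hours
from test_cohort import mini_dataset

REFSET = default_reference_trajectories()


def series_from_matrix(matrix: np.ndarray, ids=None) -> TemperatureSeriesSet:
    ids = ids or [f"H{i}" for i in range(matrix.shape[0])]
    return TemperatureSeriesSet(values=pd.DataFrame(
        matrix, index=pd.Index(ids, name="hospitalization_id"),
        columns=range(73)))


class TestSeriesConstruction:
    def _dataset_with_temps(self, rows):
        ds = mini_dataset([(hours(0), hours(80.0), "icu")])
        ds.tables["vitals"] = pd.DataFrame(
            rows, columns=["hospitalization_id", "recorded_dttm", "vital_name",
                           "vital_category", "vital_value"])
        return ds

    def _cohort(self):
        return pd.DataFrame({"hospitalization_id": ["H1"],
                             "icu_entry_dttm": [hours(0)]})

    def test_within_hour_readings_average(self):
        ds = self._dataset_with_temps([
            ("H1", hours(5.2), "TEMP C", "temp_c", 36.8),
            ("H1", hours(5.8), "TEMP C", "temp_c", 37.2)])
        series = build_temperature_series(ds, self._cohort())
        assert series.values.loc["H1", 5] == pytest.approx(37.0)

    def test_fahrenheit_converted_exactly(self):
        assert fahrenheit_to_celsius(98.6) == pytest.approx(37.0)
        ds = self._dataset_with_temps([
            ("H1", hours(2.0), "TEMP F", "temp_f", 98.6)])
        series = build_temperature_series(ds, self._cohort())
        assert series.values.loc["H1", 2] == pytest.approx(37.0)

    def test_reading_beyond_72h_ignored(self):
        ds = self._dataset_with_temps([
            ("H1", hours(1.0), "TEMP C", "temp_c", 37.0),
            ("H1", hours(72.5), "TEMP C", "temp_c", 41.0)])
        series = build_temperature_series(ds, self._cohort())
        assert series.values.loc["H1"].notna().sum() == 1

    def test_encounter_without_temperatures_excluded_with_reason(self):
        ds = self._dataset_with_temps([
            ("H1", hours(1.0), "PULSE", "heart_rate", 80.0)])
        series = build_temperature_series(ds, self._cohort())
        assert len(series) == 0
        assert series.exclusions["reason"].tolist() == [
            "no_temperature_measurements"]

    def test_exclusion_count_matches_generator_ground_truth(self):
        config = SynthConfig(n_encounters=300, seed=33, zero_temp_frac=0.05,
                             outlier_rate=0.0)
        dataset, truth = generate_dataset(config)
        cohort = discover_icu_cohort(dataset)
        series = build_temperature_series(dataset, cohort)
        expected = truth.encounters.set_index("hospitalization_id") \
            .loc[cohort["hospitalization_id"], "zero_temp"]
        assert len(series.exclusions) == int(expected.sum())
        assert set(series.exclusions["hospitalization_id"]) == set(
            expected[expected].index)

    def test_accounting_report(self):
        accounting = temperature_accounting(1000, 7)
        assert accounting["n_analyzed"] == 993
        assert accounting["pct_excluded"] == 0.7


class TestClassification:
    def test_exact_reference_match_recovers_label_with_zero_mse(self):
        matrix = np.vstack([REFSET.curves[k] for k in SUBPHENOTYPE_LABELS])
        out = classify_subphenotype(series_from_matrix(matrix), REFSET)
        assert out["assigned"].tolist() == list(SUBPHENOTYPE_LABELS)
        for i, label in enumerate(SUBPHENOTYPE_LABELS):
            assert out[f"mse_{label}"].iloc[i] == pytest.approx(0.0)

    def test_tie_breaks_in_fixed_label_order(self):
        # equidistant from every reference: constant series at the pointwise
        # mean of NT and HT gives mse_NT == mse_HT < others at hour 0 only
        flat = np.full((1, 73), np.nan)
        flat[0, 0] = (REFSET.curves["NT"][0] + REFSET.curves["HT"][0]) / 2
        out = classify_subphenotype(series_from_matrix(flat), REFSET)
        assert out["mse_NT"].iloc[0] == pytest.approx(out["mse_HT"].iloc[0])
        assert out["assigned"].iloc[0] == "NT"

    def test_matches_naive_oracle_on_random_series(self):
        rng = np.random.default_rng(77)
        n = 100
        matrix = rng.uniform(35.0, 40.0, size=(n, 73))
        matrix[rng.random((n, 73)) < 0.4] = np.nan
        matrix[np.all(np.isnan(matrix), axis=1), 0] = 37.0  # keep >=1 obs
        out = classify_subphenotype(series_from_matrix(matrix), REFSET)
        for i in range(n):
            obs = matrix[i]
            mses = {}
            for label in SUBPHENOTYPE_LABELS:
                diff = obs - REFSET.curves[label]
                mses[label] = np.nanmean(diff ** 2)
            expected = min(SUBPHENOTYPE_LABELS, key=lambda k: mses[k])
            assert out["assigned"].iloc[i] == expected
            for label in SUBPHENOTYPE_LABELS:
                assert out[f"mse_{label}"].iloc[i] == pytest.approx(mses[label])

    def test_monte_carlo_recovery_at_low_noise(self):
        """HSR + N(0, 0.2^2) noise, fully observed: label recovered >=95%."""
        rng = np.random.default_rng(2024)
        n = 1000
        matrix = REFSET.curves["HSR"][None, :] + rng.normal(0, 0.2, (n, 73))
        out = classify_subphenotype(series_from_matrix(matrix), REFSET)
        assert (out["assigned"] == "HSR").mean() >= 0.95

    def test_mse_depends_only_on_observed_values(self):
        full = REFSET.curves["HFR"].copy()[None, :]
        sparse = np.full((1, 73), np.nan)
        sparse[0, ::3] = REFSET.curves["HFR"][::3]
        dense_out = classify_subphenotype(
            series_from_matrix(full[:, :].copy()), REFSET)
        sparse_out = classify_subphenotype(series_from_matrix(sparse), REFSET)
        assert dense_out["assigned"].iloc[0] == sparse_out["assigned"].iloc[0] == "HFR"
        assert sparse_out["mse_HFR"].iloc[0] == pytest.approx(0.0)

    def test_shift_consistency(self):
        rng = np.random.default_rng(5)
        matrix = REFSET.curves["HT"][None, :] + rng.normal(0, 0.3, (20, 73))
        base = classify_subphenotype(series_from_matrix(matrix), REFSET)
        shifted_refs = ReferenceTrajectorySet(
            {k: v + 1.5 for k, v in REFSET.curves.items()})
        shifted = classify_subphenotype(
            series_from_matrix(matrix + 1.5), shifted_refs)
        assert shifted["assigned"].tolist() == base["assigned"].tolist()

    def test_zero_observation_series_rejected(self):
        empty = np.full((1, 73), np.nan)
        with pytest.raises(ValueError):
            classify_subphenotype(series_from_matrix(empty), REFSET)

    def test_assignments_exhaustive_and_exclusive(self, base_sim):
        series = build_temperature_series(base_sim.cleaned, base_sim.cohort)
        out = classify_subphenotype(series, REFSET)
        assert len(out) + len(series.exclusions) == len(base_sim.cohort)
        assert out["assigned"].isin(SUBPHENOTYPE_LABELS).all()


def simulate_regression_frame(rng, n, coef_hsr=0.0, prevalence=0.1):
    """Directly simulated assignments + covariates for the outcome model."""
    labels = rng.choice(SUBPHENOTYPE_LABELS, size=n, p=[0.5, 0.2, 0.1, 0.2])
    age = rng.normal(60, 15, n)
    sex = rng.choice(["female", "male"], n)
    race = rng.choice(["white", "black", "asian", "other"], n,
                      p=[0.6, 0.3, 0.05, 0.05])
    eth = rng.choice(["non_hispanic", "hispanic"], n, p=[0.93, 0.07])
    lp = coef_hsr * (labels == "HSR") + 0.02 * (age - 60)
    from scipy.special import expit, logit
    y = rng.random(n) < expit(logit(prevalence) + lp - lp.mean())
    assignments = pd.DataFrame({
        "hospitalization_id": [f"H{i}" for i in range(n)],
        "assigned": labels})
    cohort = pd.DataFrame({
        "hospitalization_id": assignments["hospitalization_id"],
        "age_at_admission": age, "sex_category": sex, "race_category": race,
        "ethnicity_category": eth, "in_hospital_death": y,
        "ever_imv": rng.random(n) < 0.3})
    return assignments, cohort


class TestAdjustedOutcomeModel:
    def test_reduced_model_matches_contingency_table(self):
        # no covariates, two groups: coefficient is the 2x2 log odds ratio
        rng = np.random.default_rng(12)
        n = 4000
        labels = np.where(rng.random(n) < 0.5, "NT", "HSR")
        p = np.where(labels == "HSR", 0.25, 0.10)
        y = rng.random(n) < p
        assignments = pd.DataFrame({
            "hospitalization_id": [f"H{i}" for i in range(n)],
            "assigned": labels})
        cohort = assignments[["hospitalization_id"]].copy()
        cohort["in_hospital_death"] = y
        cohort["ever_imv"] = False
        table = adjusted_outcome_model(assignments, cohort, "mortality",
                                       covariates=())
        a = ((labels == "HSR") & y).sum()
        b = ((labels == "HSR") & ~y).sum()
        c = ((labels == "NT") & y).sum()
        d = ((labels == "NT") & ~y).sum()
        expected_or = (a * d) / (b * c)
        got = table.set_index("term").loc["subphenotype[hsr]", "odds_ratio"]
        assert got == pytest.approx(expected_or, rel=1e-6)

    def test_or_equals_exp_coefficient_and_ci_from_se(self):
        rng = np.random.default_rng(3)
        assignments, cohort = simulate_regression_frame(rng, 3000, coef_hsr=0.5)
        table = adjusted_outcome_model(assignments, cohort, "mortality")
        for _, row in table.iterrows():
            assert row["odds_ratio"] == pytest.approx(np.exp(row["coefficient"]))
            assert row["ci_low"] == pytest.approx(
                np.exp(row["coefficient"] - 1.96 * row["se"]))

    def test_null_association_ci_coverage(self):
        """With outcome independent of subphenotype, the HSR CI covers 1.0
        in at least 90% of seeded replicates."""
        rng = np.random.default_rng(88)
        covered = 0
        n_rep = 100
        for _ in range(n_rep):
            assignments, cohort = simulate_regression_frame(rng, 1200,
                                                            coef_hsr=0.0)
            table = adjusted_outcome_model(assignments, cohort, "mortality") \
                .set_index("term")
            lo = table.loc["subphenotype[hsr]", "ci_low"]
            hi = table.loc["subphenotype[hsr]", "ci_high"]
            covered += (lo <= 1.0 <= hi)
        assert covered >= 0.90 * n_rep

    def test_perfect_separation_reported_as_failure(self):
        assignments = pd.DataFrame({
            "hospitalization_id": [f"H{i}" for i in range(40)],
            "assigned": ["NT"] * 20 + ["HSR"] * 20})
        cohort = assignments[["hospitalization_id"]].copy()
        cohort["in_hospital_death"] = [False] * 20 + [True] * 20
        cohort["ever_imv"] = False
        with pytest.raises(FitFailureError):
            adjusted_outcome_model(assignments, cohort, "mortality",
                                   covariates=())

    def test_single_class_outcome_rejected(self):
        assignments = pd.DataFrame({"hospitalization_id": ["H1", "H2"],
                                    "assigned": ["NT", "HSR"]})
        cohort = assignments[["hospitalization_id"]].copy()
        cohort["in_hospital_death"] = False
        cohort["ever_imv"] = False
        with pytest.raises(FitFailureError):
            adjusted_outcome_model(assignments, cohort, "mortality",
                                   covariates=())
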