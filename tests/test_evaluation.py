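"""Discrimination, calibration and decision-curve metrics."""

import json
import warnings

import numpy as np
import pytest
from scipy.stats import norm

from clifkit import (
    EvaluationReport,
    auc,
    auc_ci,
    brier,
    calibration_curve,
    decision_curve,
    evaluate_predictions,
    evaluate_site,
    net_benefit,
)


class TestAuc:
    def test_perfect_separation(self):
        assert auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_pure_ties_give_half(self):
        assert auc([0.4] * 6, [1, 1, 1, 0, 0, 0]) == 0.5

    def test_matches_pairwise_oracle_exactly(self):
        rng = np.random.default_rng(10)
        for _ in range(50):
            n = int(rng.integers(6, 40))
            scores = np.round(rng.random(n), 2)  # induce ties
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            pos = scores[labels == 1][:, None]
            neg = scores[labels == 0][None, :]
            oracle = (np.sum(pos > neg) + 0.5 * np.sum(pos == neg)) \
                / (pos.size * neg.size)
            assert auc(scores, labels) == pytest.approx(oracle, abs=1e-12)

    def test_complement_identity_tie_free(self):
        rng = np.random.default_rng(4)
        scores = rng.normal(size=80)
        labels = rng.integers(0, 2, 80)
        labels[:2] = [0, 1]
        assert auc(scores, labels) + auc(-scores, labels) == pytest.approx(1.0)

    def test_agrees_with_sklearn(self):
        from sklearn.metrics import roc_auc_score
        rng = np.random.default_rng(11)
        scores = rng.random(200)
        labels = rng.integers(0, 2, 200)
        assert auc(scores, labels) == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc([0.1, 0.9], [1, 1])


class TestAucCi:
    def test_perfect_separation_upper_bound_one(self):
        scores = np.r_[np.linspace(0.6, 0.9, 50), np.linspace(0.1, 0.4, 50)]
        labels = np.r_[np.ones(50), np.zeros(50)]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            lo, hi = auc_ci(scores, labels)
        assert hi == 1.0

    def test_interval_contains_point_estimate(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            scores = rng.normal(size=60) + np.r_[np.full(30, 0.5), np.zeros(30)]
            labels = np.r_[np.ones(30), np.zeros(30)]
            lo, hi = auc_ci(scores, labels)
            assert lo <= auc(scores, labels) <= hi

    def test_bootstrap_option_agrees_with_delong(self):
        rng = np.random.default_rng(17)
        scores = np.r_[rng.normal(1.0, 1, 150), rng.normal(0, 1, 150)]
        labels = np.r_[np.ones(150), np.zeros(150)]
        d_lo, d_hi = auc_ci(scores, labels)
        b_lo, b_hi = auc_ci(scores, labels, method="bootstrap", n_boot=500,
                            seed=2)
        assert b_lo == pytest.approx(d_lo, abs=0.04)
        assert b_hi == pytest.approx(d_hi, abs=0.04)
        # seeded: reproducible
        assert auc_ci(scores, labels, method="bootstrap", n_boot=500,
                      seed=2) == (b_lo, b_hi)

    def test_coverage_near_nominal(self):
        """95% CI covers a known true AUC of 0.75 in 95% +/- 3% of sims."""
        mu = np.sqrt(2.0) * norm.ppf(0.75)   # binormal model with AUC 0.75
        rng = np.random.default_rng(123)
        covered = 0
        n_sim = 500
        for _ in range(n_sim):
            pos = rng.normal(mu, 1.0, 100)
            neg = rng.normal(0.0, 1.0, 100)
            lo, hi = auc_ci(np.r_[pos, neg], np.r_[np.ones(100), np.zeros(100)])
            covered += (lo <= 0.75 <= hi)
        assert covered / n_sim == pytest.approx(0.95, abs=0.03)


class TestBrier:
    def test_perfect_predictions(self):
        assert brier([1.0, 0.0, 1.0], [1, 0, 1]) == 0.0

    def test_constant_half(self):
        assert brier([0.5] * 10, [1] * 4 + [0] * 6) == pytest.approx(0.25)

    @pytest.mark.parametrize("p,pi", [(0.2, 0.1), (0.5, 0.3), (0.9, 0.7)])
    def test_constant_predictor_closed_form(self, p, pi):
        n = 1000
        k = int(round(pi * n))
        labels = np.r_[np.ones(k), np.zeros(n - k)]
        expected = (k / n) * (1 - p) ** 2 + (1 - k / n) * p ** 2
        assert brier(np.full(n, p), labels) == pytest.approx(expected)

    def test_agrees_with_sklearn(self):
        from sklearn.metrics import brier_score_loss
        rng = np.random.default_rng(2)
        scores = rng.random(150)
        labels = rng.integers(0, 2, 150)
        assert brier(scores, labels) == pytest.approx(
            brier_score_loss(labels, scores), abs=1e-12)

    def test_scores_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            brier([1.2], [1])


class TestCalibrationCurve:
    def test_well_calibrated_scores(self):
        rng = np.random.default_rng(9)
        scores = rng.uniform(0.05, 0.95, 5000)
        labels = rng.random(5000) < scores
        bins = calibration_curve(scores, labels)
        for _, row in bins.iterrows():
            se = np.sqrt(row["mean_predicted"] * (1 - row["mean_predicted"])
                         / row["n"])
            assert abs(row["mean_predicted"] - row["observed_rate"]) < 3 * se

    def test_all_negative_labels(self):
        scores = np.linspace(0.1, 0.9, 40)
        bins = calibration_curve(scores, np.zeros(40))
        assert (bins["observed_rate"] == 0).all()

    def test_bin_counts_sum_to_n(self):
        rng = np.random.default_rng(1)
        bins = calibration_curve(rng.random(123), rng.integers(0, 2, 123))
        assert bins["n"].sum() == 123
        assert len(bins) == 10

    def test_small_sample_warns_and_shrinks(self):
        with pytest.warns(UserWarning):
            bins = calibration_curve([0.2, 0.8, 0.5], [0, 1, 1], n_bins=10)
        assert len(bins) == 3


class TestNetBenefit:
    def test_treat_all_at_printed_prevalence_endpoints(self):
        labels_low = np.r_[np.ones(74), np.zeros(926)]    # prevalence 7.4%
        labels_high = np.r_[np.ones(130), np.zeros(870)]  # prevalence 13%
        scores = np.full(1000, 0.99)
        low = net_benefit(scores, labels_low, 0.3)
        high = net_benefit(scores, labels_high, 0.3)
        assert round(low.net_benefit_treat_all, 2) == -0.32
        assert round(high.net_benefit_treat_all, 2) == -0.24
        assert low.net_benefit_treat_none == 0.0

    def test_perfect_classifier_net_benefit_equals_prevalence(self):
        labels = np.r_[np.ones(30), np.zeros(70)]
        scores = labels.astype(float)
        for p_t in (0.1, 0.3, 0.6, 0.9):
            point = net_benefit(scores, labels, p_t)
            assert point.net_benefit_model == pytest.approx(0.3)

    def test_classify_everyone_positive_reduces_to_treat_all(self):
        rng = np.random.default_rng(14)
        labels = rng.integers(0, 2, 200)
        scores = rng.uniform(0.90, 1.0, 200)   # all >= threshold
        point = net_benefit(scores, labels, 0.3)
        assert point.net_benefit_model == pytest.approx(
            point.net_benefit_treat_all)

    def test_treat_all_tends_to_prevalence_at_small_threshold(self):
        labels = np.r_[np.ones(25), np.zeros(75)]
        point = net_benefit(np.full(100, 0.5), labels, 1e-6)
        assert point.net_benefit_treat_all == pytest.approx(0.25, abs=1e-5)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        scores = rng.random(100)
        labels = rng.integers(0, 2, 100)
        perm = rng.permutation(100)
        a = net_benefit(scores, labels, 0.3)
        b = net_benefit(scores[perm], labels[perm], 0.3)
        assert a == b

    def test_threshold_bounds(self):
        with pytest.raises(ValueError):
            net_benefit([0.5], [1], 0.0)


class TestSiteReport:
    def test_auc_close_to_theoretical_truth(self):
        # binormal scores: theoretical AUC = Phi(mu / sqrt(2))
        mu = 1.2
        truth = norm.cdf(mu / np.sqrt(2.0))
        rng = np.random.default_rng(21)
        n = 4000
        pos = rng.normal(mu, 1.0, n)
        neg = rng.normal(0.0, 1.0, n)
        scores = 1.0 / (1.0 + np.exp(-np.r_[pos, neg]))
        labels = np.r_[np.ones(n), np.zeros(n)]
        report = evaluate_predictions(scores, labels)
        se = np.sqrt((2 * n + 1) / (12.0 * n * n))
        assert report.auc == pytest.approx(truth, abs=3 * max(se, 0.012))

    def test_json_round_trip_lossless(self, tmp_path):
        rng = np.random.default_rng(30)
        scores = rng.random(300)
        labels = rng.integers(0, 2, 300)
        report = evaluate_predictions(scores, labels, site="demo")
        path = tmp_path / "report.json"
        report.to_json(path)
        assert EvaluationReport.from_json(path) == report
        assert EvaluationReport.from_json(report.to_json()) == report

    def test_full_site_evaluation(self, trained_sim):
        report = evaluate_site(trained_sim.model, trained_sim.dataset,
                               trained_sim.cohort)
        assert report.n == len(trained_sim.cohort)
        thresholds = [p["threshold"] for p in report.decision_curve]
        assert 0.3 in thresholds
        assert all(p["net_benefit_treat_none"] == 0.0
                   for p in report.decision_curve)
        assert 0.0 <= report.auc <= 1.0 and 0.0 <= report.brier <= 1.0

    def test_empty_cohort_rejected(self, trained_sim):
        import pandas as pd
        with pytest.raises(ValueError):
            evaluate_site(trained_sim.model, trained_sim.dataset,
                          pd.DataFrame(columns=trained_sim.cohort.columns))
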