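"""Prognostic-model validation: discrimination, calibration, clinical utility.

One site's validation report covers the three axes used to judge a risk
model in external validation:

* discrimination — the area under the ROC curve via the rank (Mann-Whitney)
  estimator ``P(score_pos > score_neg) + 0.5 * P(tie)``, with a DeLong
  variance-based 95% CI;
* calibration — the Brier score (mean squared error of the predicted
  probability) and a decile calibration curve (equal-count bins, mean
  predicted vs observed event rate);
* clinical utility — decision-curve analysis. At threshold probability
  ``p_t`` the net benefit of a classifier that treats patients with
  ``score >= p_t`` is ``TP/N - (FP/N) * p_t/(1-p_t)``; the treat-all
  strategy has ``pi - (1-pi) * p_t/(1-p_t)`` at prevalence ``pi`` and
  treat-none is 0 by definition.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import rankdata


def _check_binary(labels: np.ndarray) -> None:
    classes = np.unique(labels)
    if not np.all(np.isin(classes, (0, 1))):
        raise ValueError("labels must be binary 0/1")
    if classes.size < 2:
        raise ValueError("both outcome classes must be present")


def _as_arrays(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float).astype(int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    return scores, labels


# ---------------------------------------------------------------------------
# Discrimination
# ---------------------------------------------------------------------------

def auc(scores, labels) -> float:
    """Rank-based AUC: ``P(score_pos > score_neg) + 0.5 P(tie)``."""
    scores, labels = _as_arrays(scores, labels)
    _check_binary(labels)
    m = int(labels.sum())
    n = labels.size - m
    ranks = rankdata(scores)           # midranks handle ties
    return float((ranks[labels == 1].sum() - m * (m + 1) / 2.0) / (m * n))


def _delong_variance(scores: np.ndarray, labels: np.ndarray):
    """DeLong placement-value variance of the AUC estimator."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = pos.size, neg.size
    all_ranks = rankdata(np.concatenate([pos, neg]))
    pos_ranks = rankdata(pos)
    neg_ranks = rankdata(neg)
    v_pos = (all_ranks[:m] - pos_ranks) / n          # placements of positives
    v_neg = 1.0 - (all_ranks[m:] - neg_ranks) / m    # placements of negatives
    a = float(v_pos.mean())
    s_pos = float(np.var(v_pos, ddof=1)) if m > 1 else 0.0
    s_neg = float(np.var(v_neg, ddof=1)) if n > 1 else 0.0
    return a, s_pos / m + s_neg / n


def auc_ci(scores, labels, alpha: float = 0.05, method: str = "delong",
           n_boot: int = 2000, seed: int = 0):
    """95% (by default) confidence interval for the AUC, truncated to [0, 1].

    ``method="delong"`` (default) uses the analytic placement-value
    variance; ``method="bootstrap"`` uses a seeded stratified percentile
    bootstrap with ``n_boot`` resamples. For DeLong, a degenerate (zero)
    variance cannot support a Wald interval; the widest valid interval is
    returned with a warning.
    """
    scores, labels = _as_arrays(scores, labels)
    _check_binary(labels)
    if (labels == 1).sum() < 2 or (labels == 0).sum() < 2:
        raise ValueError("need at least two members of each class")
    if method == "bootstrap":
        rng = np.random.default_rng(seed)
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        stats = np.empty(n_boot)
        ones = np.ones(pos.size)
        zeros = np.zeros(neg.size)
        lab = np.concatenate([ones, zeros])
        for b in range(n_boot):
            sample = np.concatenate([rng.choice(pos, pos.size, replace=True),
                                     rng.choice(neg, neg.size, replace=True)])
            stats[b] = auc(sample, lab)
        lo, hi = np.quantile(stats, [alpha / 2.0, 1.0 - alpha / 2.0])
        return (float(max(0.0, lo)), float(min(1.0, hi)))
    if method != "delong":
        raise ValueError("method must be 'delong' or 'bootstrap'")
    from scipy.stats import norm
    a, var = _delong_variance(scores, labels)
    if var <= 0.0:
        warnings.warn("degenerate DeLong variance; returning the widest "
                      "valid interval", stacklevel=2)
        return (0.0, 1.0)
    z = norm.ppf(1.0 - alpha / 2.0)
    half = z * np.sqrt(var)
    return (float(max(0.0, a - half)), float(min(1.0, a + half)))


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

def brier(scores, labels) -> float:
    """Mean of (score - label)^2; scores must be probabilities in [0, 1]."""
    scores, labels = _as_arrays(scores, labels)
    if np.any((scores < 0) | (scores > 1)):
        raise ValueError("scores must lie in [0, 1]")
    return float(np.mean((scores - labels) ** 2))


def calibration_curve(scores, labels, n_bins: int = 10) -> pd.DataFrame:
    """Equal-count calibration bins (deciles of predicted risk by default).

    Returns a DataFrame with ``bin``, ``mean_predicted``, ``observed_rate``
    and ``n``; bin counts sum to the number of subjects. Fewer bins are
    used (with a warning) when there are fewer subjects than bins.
    """
    scores, labels = _as_arrays(scores, labels)
    if scores.size == 0:
        raise ValueError("empty input")
    if scores.size < n_bins:
        warnings.warn(f"only {scores.size} subjects; using that many bins",
                      stacklevel=2)
        n_bins = scores.size
    order = np.argsort(scores, kind="mergesort")
    splits = np.array_split(order, n_bins)
    rows = []
    for i, idx in enumerate(splits):
        rows.append({
            "bin": i,
            "mean_predicted": float(scores[idx].mean()),
            "observed_rate": float(labels[idx].mean()),
            "n": int(idx.size),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Decision-curve analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DecisionCurvePoint:
    """Net benefit of the model, treat-all and treat-none strategies at one
    threshold probability."""

    threshold: float
    net_benefit_model: float
    net_benefit_treat_all: float
    net_benefit_treat_none: float = 0.0


def net_benefit(scores, labels, p_t: float) -> DecisionCurvePoint:
    """Decision-curve point at threshold probability ``p_t``.

    A subject is classified positive iff ``score >= p_t``. With N subjects,
    ``NB_model = TP/N - (FP/N) * p_t/(1-p_t)``; treat-all gives
    ``pi - (1-pi) * p_t/(1-p_t)`` at prevalence ``pi``; treat-none is 0.
    """
    if not 0.0 < p_t < 1.0:
        raise ValueError("p_t must lie strictly inside (0, 1)")
    scores, labels = _as_arrays(scores, labels)
    n = scores.size
    if n == 0:
        raise ValueError("empty input")
    w = p_t / (1.0 - p_t)
    positive = scores >= p_t
    tp = float((positive & (labels == 1)).sum())
    fp = float((positive & (labels == 0)).sum())
    pi = float(labels.mean())
    return DecisionCurvePoint(
        threshold=float(p_t),
        net_benefit_model=tp / n - (fp / n) * w,
        net_benefit_treat_all=pi - (1.0 - pi) * w,
    )


def decision_curve(scores, labels, thresholds) -> list:
    return [net_benefit(scores, labels, float(p)) for p in thresholds]


# ---------------------------------------------------------------------------
# Site report
# ---------------------------------------------------------------------------

#: a-priori high-risk decision threshold used in the mortality case study
HIGH_RISK_THRESHOLD = 0.3

DEFAULT_THRESHOLD_GRID = tuple(np.round(np.arange(0.05, 0.96, 0.05), 2))


@dataclass
class EvaluationReport:
    """Full validation report for one site."""

    site: str
    n: int
    prevalence: float
    auc: float
    auc_ci_low: float
    auc_ci_high: float
    brier: float
    calibration: list = field(default_factory=list)     # list of bin dicts
    decision_curve: list = field(default_factory=list)  # list of point dicts

    def __post_init__(self) -> None:
        if not 0.0 <= self.auc <= 1.0:
            raise ValueError("auc must lie in [0, 1]")
        if not 0.0 <= self.brier <= 1.0:
            raise ValueError("brier must lie in [0, 1]")

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "EvaluationReport":
        from ._io import load_json_source
        return cls(**load_json_source(source))

    def calibration_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.calibration)

    def decision_curve_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.decision_curve)


def evaluate_predictions(scores, labels, site: str = "site",
                         thresholds=DEFAULT_THRESHOLD_GRID,
                         n_bins: int = 10) -> EvaluationReport:
    """Build a full report from per-subject risks and outcomes."""
    scores, labels = _as_arrays(scores, labels)
    points = decision_curve(scores, labels, thresholds)
    ci_low, ci_high = auc_ci(scores, labels)
    return EvaluationReport(
        site=site,
        n=int(scores.size),
        prevalence=float(labels.mean()),
        auc=auc(scores, labels),
        auc_ci_low=ci_low,
        auc_ci_high=ci_high,
        brier=brier(scores, labels),
        calibration=calibration_curve(scores, labels, n_bins).to_dict("records"),
        decision_curve=[asdict(p) for p in points],
    )


def evaluate_site(model, dataset, cohort, spec=None,
                  thresholds=DEFAULT_THRESHOLD_GRID) -> EvaluationReport:
    """Federated-style site evaluation: extract first-24-h features with the
    model's spec, score the cohort, and report discrimination, calibration
    and the decision curve (the grid includes the 0.3 high-risk threshold).
    """
    from .features import extract_features, predict_risk, default_feature_spec
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    spec = spec or default_feature_spec()
    matrix = extract_features(dataset, cohort, spec)
    scores = predict_risk(model, matrix)
    labels = matrix["in_hospital_death"].to_numpy(dtype=float)
    thresholds = sorted(set(float(t) for t in thresholds) | {HIGH_RISK_THRESHOLD})
    return evaluate_predictions(scores, labels, site=dataset.site_label,
                                thresholds=thresholds)


# ---------------------------------------------------------------------------
# Plots (ROC / calibration / decision curve panels)
# ---------------------------------------------------------------------------

def plot_report(report: EvaluationReport, path=None):
    """Three-panel figure: ROC-style summary, calibration, decision curve."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=(13, 4))
    axes[0].bar(["AUC"], [report.auc])
    axes[0].errorbar([0], [report.auc],
                     yerr=[[report.auc - report.auc_ci_low],
                           [report.auc_ci_high - report.auc]],
                     fmt="none", ecolor="black", capsize=4)
    axes[0].set_ylim(0, 1)
    axes[0].set_title(f"Discrimination ({report.site})")

    cal = report.calibration_frame()
    axes[1].plot([0, 1], [0, 1], "k--", lw=1)
    axes[1].plot(cal["mean_predicted"], cal["observed_rate"], "o-")
    axes[1].set_xlabel("mean predicted risk")
    axes[1].set_ylabel("observed rate")
    axes[1].set_title(f"Calibration (Brier {report.brier:.3f})")

    dc = report.decision_curve_frame()
    axes[2].plot(dc["threshold"], dc["net_benefit_model"], label="model")
    axes[2].plot(dc["threshold"], dc["net_benefit_treat_all"], label="treat all")
    axes[2].axhline(0.0, color="k", lw=1, label="treat none")
    axes[2].set_ylim(-0.35, max(0.3, report.prevalence + 0.05))
    axes[2].set_xlabel("threshold probability")
    axes[2].set_ylabel("net benefit")
    axes[2].legend()
    axes[2].set_title("Decision curve")

    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
        plt.close(fig)
    return fig
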