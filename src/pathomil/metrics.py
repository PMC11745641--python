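"""Discrimination and prognostic-stratification metrics.

ROC/AUC for the LNM classifier; cumulative-case / dynamic-control AUCs at
fixed horizons for the DFS risk score; median-split risk groups;
Kaplan-Meier survival curves; and the two-sample log-rank test. The heavy
lifting goes through scikit-learn and lifelines; the test suite holds the
independent brute-force oracles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from sklearn.metrics import roc_auc_score, roc_curve

__all__ = [
    "UndefinedMetricError",
    "RocResult",
    "KmCurve",
    "roc_auc",
    "horizon_auc",
    "dichotomize",
    "km_estimate",
    "logrank",
    "concordance_with_class",
]


class UndefinedMetricError(ValueError):
    """Raised when a metric has no defined value (e.g. one class absent)."""


@dataclass
class RocResult:
    auc: float
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray


@dataclass
class KmCurve:
    """Product-limit survival estimate: steps only at event times."""

    times: np.ndarray  # unique event times, ascending
    survival: np.ndarray  # S(t) at those times, nonincreasing, starts <= 1
    at_risk: np.ndarray  # risk-set size just before each event time


def roc_auc(scores, labels) -> RocResult:
    """ROC curve and AUC (Mann-Whitney normalization; ties count one half)."""
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels, dtype=float).ravel()
    classes = np.unique(labels)
    if classes.size < 2:
        raise UndefinedMetricError("ROC AUC needs both classes present")
    fpr, tpr, thr = roc_curve(labels, scores)
    return RocResult(auc=float(roc_auc_score(labels, scores)), fpr=fpr, tpr=tpr, thresholds=thr)


def horizon_auc(risk_scores, times, events, horizon: float) -> float:
    """Time-dependent AUC at a fixed horizon (months).

    Cases are subjects with an observed event by the horizon; controls are
    subjects still under observation past it. Subjects censored before the
    horizon are excluded (no inverse-probability weighting).
    """
    risk_scores = np.asarray(risk_scores, dtype=float).ravel()
    times = np.asarray(times, dtype=float).ravel()
    events = np.asarray(events, dtype=float).ravel()
    case = (events == 1) & (times <= horizon)
    control = times > horizon
    retained = case | control
    if not case.any() or not control.any():
        raise UndefinedMetricError(f"no cases or no controls at horizon {horizon}")
    return roc_auc(risk_scores[retained], case[retained].astype(float)).auc


def dichotomize(train_risks, eval_risks) -> np.ndarray:
    """Median-split risk groups: threshold at the training-set median.

    Returns an array of ``"high"`` / ``"low"``; a risk exactly at the
    threshold goes to the low group.
    """
    train_risks = np.asarray(train_risks, dtype=float).ravel()
    if train_risks.size == 0:
        raise ValueError("train_risks must be non-empty")
    threshold = float(np.median(train_risks))
    eval_risks = np.asarray(eval_risks, dtype=float).ravel()
    return np.where(eval_risks > threshold, "high", "low")


def km_estimate(times, events) -> KmCurve:
    """Kaplan-Meier product-limit estimator of the survival function."""
    times = np.asarray(times, dtype=float).ravel()
    events = np.asarray(events, dtype=float).ravel()
    if times.size < 1:
        raise ValueError("need at least one subject")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    event_times = np.unique(times[events == 1])
    if event_times.size == 0:
        return KmCurve(times=event_times, survival=np.ones(0), at_risk=np.zeros(0, dtype=int))
    survival = kmf.survival_function_at_times(event_times).to_numpy()
    at_risk = np.array([(times >= t).sum() for t in event_times])
    return KmCurve(times=event_times, survival=survival, at_risk=at_risk)


def logrank(times, events, groups) -> tuple[float, float]:
    """Two-sample log-rank test; returns (chi_square, p_value)."""
    times = np.asarray(times, dtype=float).ravel()
    events = np.asarray(events, dtype=float).ravel()
    groups = np.asarray(groups).ravel()
    labels = np.unique(groups)
    if labels.size != 2:
        raise ValueError(f"log-rank needs exactly two non-empty groups, got {labels.size}")
    if events.sum() == 0:
        raise UndefinedMetricError("log-rank test undefined with no events")
    a = groups == labels[0]
    result = logrank_test(times[a], times[~a], event_observed_A=events[a], event_observed_B=events[~a])
    return float(result.test_statistic), float(result.p_value)


def concordance_with_class(risk_scores, binary_class) -> float:
    """Probability a random positive-class subject outranks a negative one.

    Equivalent to the AUC of the risk score against the binary class; used
    to check that higher predicted risk tracks the adverse latent class.
    """
    return roc_auc(risk_scores, binary_class).auc
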