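"""Classification and survival metric battery.

Confusion metrics at a cutoff, ROC/AUC with the Youden-optimal cutoff,
Harrell's concordance index (with bootstrap optimism correction), Brier
score, calibration bins, decision-curve net benefit, Kaplan-Meier and
log-rank, and cumulative/dynamic time-dependent AUC with inverse
probability-of-censoring weights.

Undefined metrics (zero denominators) surface as ``None`` markers, never
silently as 0.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Callable, Sequence

import numpy as np
from sklearn.metrics import roc_auc_score

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "RocCurve",
    "confusion_at_cutoff",
    "classification_metrics",
    "roc_auc",
    "youden_cutoff",
    "harrell_c",
    "brier_score",
    "calibration_bins",
    "decision_curve",
    "km_curve",
    "logrank",
    "time_dependent_auc",
    "bootstrap_cindex",
]


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricReport:
    """The study's metric column set; ``None`` marks undefined entries."""

    auc: float | None = None
    c_index: float | None = None
    sensitivity: float | None = None
    specificity: float | None = None
    accuracy: float | None = None
    precision: float | None = None
    npv: float | None = None
    f1: float | None = None
    youden_j: float | None = None
    brier: float | None = None

    def as_dict(self) -> dict:
        return asdict(self)


def _check_scores_labels(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if scores.shape[0] != labels.shape[0]:
        raise ValueError("scores and labels length mismatch")
    if scores.shape[0] == 0:
        raise ValueError("empty input")
    return scores, labels


def confusion_at_cutoff(scores, labels, cutoff: float) -> ConfusionCounts:
    """Counts with the convention *predicted positive iff score >= cutoff*."""
    scores, labels = _check_scores_labels(scores, labels)
    pred = scores >= cutoff
    pos = labels == 1
    return ConfusionCounts(
        tp=int(np.sum(pred & pos)),
        fp=int(np.sum(pred & ~pos)),
        tn=int(np.sum(~pred & ~pos)),
        fn=int(np.sum(~pred & pos)),
    )


def _ratio(num: float, den: float) -> float | None:
    return num / den if den > 0 else None


def classification_metrics(c: ConfusionCounts) -> MetricReport:
    """Sensitivity, specificity, accuracy, precision, NPV, F1, Youden J.

    F1 is computed from precision and sensitivity; Youden's J is
    sensitivity + specificity - 1. Zero-denominator metrics are ``None``.
    """
    sens = _ratio(c.tp, c.tp + c.fn)
    spec = _ratio(c.tn, c.tn + c.fp)
    acc = _ratio(c.tp + c.tn, c.n)
    prec = _ratio(c.tp, c.tp + c.fp)
    npv = _ratio(c.tn, c.tn + c.fn)
    f1 = None
    if prec is not None and sens is not None and (prec + sens) > 0:
        f1 = 2 * prec * sens / (prec + sens)
    j = sens + spec - 1 if (sens is not None and spec is not None) else None
    return MetricReport(
        sensitivity=sens, specificity=spec, accuracy=acc,
        precision=prec, npv=npv, f1=f1, youden_j=j,
    )


@dataclass
class RocCurve:
    """Cutoff sweep over the observed scores (descending thresholds)."""

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float


def roc_auc(scores, labels) -> RocCurve:
    """ROC curve and AUC (= P(score+ > score-) + half the tie mass)."""
    scores, labels = _check_scores_labels(scores, labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    auc = float(roc_auc_score(labels, scores))
    thresholds = np.unique(scores)[::-1]
    pos = labels == 1
    n_pos, n_neg = pos.sum(), (~pos).sum()
    tpr = np.array([(scores[pos] >= t).mean() for t in thresholds])
    fpr = np.array([(scores[~pos] >= t).mean() for t in thresholds])
    del n_pos, n_neg
    return RocCurve(thresholds=thresholds, tpr=tpr, fpr=fpr, auc=auc)


def youden_cutoff(roc: RocCurve) -> float:
    """Threshold maximizing J = TPR - FPR; ties go to the smallest cutoff."""
    j = roc.tpr - roc.fpr
    best = j.max()
    candidates = roc.thresholds[j >= best - 1e-12]
    return float(candidates.min())


def harrell_c(risk, time, event) -> float:
    """Harrell's concordance over comparable pairs.

    A pair (i, j) with ``t_i < t_j`` and ``event_i`` is concordant when
    ``risk_i > risk_j``; tied risks earn half credit. Pairs where the
    earlier time is censored are not comparable.
    """
    risk = np.asarray(risk, float)
    time = np.asarray(time, float)
    event = np.asarray(event).astype(bool)
    t_i = time[:, None]
    comparable = (t_i < time[None, :]) & event[:, None]
    n_pairs = comparable.sum()
    if n_pairs == 0:
        raise ValueError("no comparable pairs")
    r_i = risk[:, None]
    conc = (r_i > risk[None, :]) & comparable
    ties = (r_i == risk[None, :]) & comparable
    return float((conc.sum() + 0.5 * ties.sum()) / n_pairs)


def brier_score(probabilities, labels) -> float:
    """Mean squared error between predicted probability and outcome."""
    p, y = _check_scores_labels(probabilities, labels)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must be in [0, 1]")
    return float(np.mean((p - y) ** 2))


def calibration_bins(probabilities, labels, n_bins: int = 10):
    """Equal-width bins on [0, 1]; empty bins are omitted.

    Returns a list of ``(mean_predicted, observed_rate, count)`` tuples.
    """
    p, y = _check_scores_labels(probabilities, labels)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.clip(np.digitize(p, edges[1:-1]), 0, n_bins - 1)
    out = []
    for b in range(n_bins):
        mask = idx == b
        if mask.any():
            out.append((float(p[mask].mean()), float(y[mask].mean()), int(mask.sum())))
    return out


def decision_curve(probabilities, labels, thresholds):
    """Net benefit of acting on the model at each threshold probability.

    ``NB(pt) = TP/n - (FP/n) * pt/(1-pt)`` with predicted positive iff
    probability >= pt; also returns the treat-all and treat-none
    references. Thresholds outside (0, 1) raise; pt = 1 is excluded by
    construction.
    """
    p, y = _check_scores_labels(probabilities, labels)
    thresholds = np.asarray(thresholds, float)
    if np.any((thresholds <= 0) | (thresholds >= 1)):
        raise ValueError("thresholds must lie strictly inside (0, 1)")
    n = len(p)
    prevalence = y.mean()
    model_nb, all_nb = [], []
    for pt in thresholds:
        c = confusion_at_cutoff(p, y, pt)
        odds = pt / (1 - pt)
        model_nb.append(c.tp / n - (c.fp / n) * odds)
        all_nb.append(prevalence - (1 - prevalence) * odds)
    return {
        "thresholds": thresholds,
        "model": np.array(model_nb),
        "treat_all": np.array(all_nb),
        "treat_none": np.zeros_like(thresholds),
    }


def km_curve(time, event):
    """Kaplan-Meier product-limit estimate.

    Returns ``(times, survival)`` step-function arrays (survival value at
    and after each event time).
    """
    from lifelines import KaplanMeierFitter

    time = np.asarray(time, float)
    if len(time) == 0:
        raise ValueError("empty group")
    kmf = KaplanMeierFitter()
    kmf.fit(time, np.asarray(event).astype(int))
    sf = kmf.survival_function_
    return sf.index.to_numpy(dtype=float), sf.iloc[:, 0].to_numpy(dtype=float)


def logrank(time_a, event_a, time_b, event_b) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p-value)."""
    from lifelines.statistics import logrank_test

    if len(np.asarray(time_a)) == 0 or len(np.asarray(time_b)) == 0:
        raise ValueError("both groups must be nonempty")
    res = logrank_test(
        time_a, time_b,
        event_observed_A=np.asarray(event_a).astype(int),
        event_observed_B=np.asarray(event_b).astype(int),
    )
    return float(res.test_statistic), float(res.p_value)


def _censoring_survival(time, event):
    """KM estimate of the censoring distribution G(t) (events flipped)."""
    from lifelines import KaplanMeierFitter

    kmf = KaplanMeierFitter()
    kmf.fit(np.asarray(time, float), 1 - np.asarray(event).astype(int))
    return kmf


def time_dependent_auc(marker, time, event, horizon: float) -> float:
    """Cumulative/dynamic AUC at ``horizon`` with IPCW case weights.

    Cases are subjects with an observed event by the horizon, weighted by
    ``1/G(T-)`` where G is the Kaplan-Meier censoring survival; controls
    are subjects still at risk beyond the horizon. With no censoring this
    reduces exactly to the binary AUC of the labels ``1{T <= horizon}``.
    """
    marker = np.asarray(marker, float)
    time = np.asarray(time, float)
    event = np.asarray(event).astype(bool)
    cases = (time <= horizon) & event
    controls = time > horizon
    if cases.sum() == 0:
        raise ValueError("no events before the horizon")
    if controls.sum() == 0:
        raise ValueError("no subjects at risk beyond the horizon")
    G = _censoring_survival(time, event)
    g_case = np.clip(
        G.survival_function_at_times(time[cases] - 1e-12).to_numpy(), 1e-12, None
    )
    w = 1.0 / g_case
    mc = marker[cases]
    mk = marker[controls]
    greater = (mc[:, None] > mk[None, :]).astype(float)
    ties = (mc[:, None] == mk[None, :]).astype(float)
    num = (w[:, None] * (greater + 0.5 * ties)).sum()
    den = w.sum() * len(mk)
    return float(num / den)


def bootstrap_cindex(
    fit_procedure: Callable,
    records: Sequence,
    time,
    event,
    B: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """Harrell optimism-corrected concordance.

    ``fit_procedure(records_subset, time_subset, event_subset)`` must
    return a scoring callable ``risk(records, time, event) -> scores``.
    Returns (apparent c, optimism-corrected c).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    records = list(records)
    time = np.asarray(time, float)
    event = np.asarray(event).astype(bool)
    n = len(records)
    rng = np.random.default_rng(seed)

    score_full = fit_procedure(records, time, event)
    apparent = harrell_c(score_full(records, time, event), time, event)
    optimisms = []
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        # resample until the draw has an event and a comparable pair
        for _ in range(1000):
            if event[idx].any() and len(np.unique(time[idx])) > 1:
                break
            idx = rng.integers(0, n, size=n)
        rec_b = [records[i] for i in idx]
        t_b, e_b = time[idx], event[idx]
        score_b = fit_procedure(rec_b, t_b, e_b)
        c_boot = harrell_c(score_b(rec_b, t_b, e_b), t_b, e_b)
        c_orig = harrell_c(score_b(records, time, event), time, event)
        optimisms.append(c_boot - c_orig)
    return float(apparent), float(apparent - np.mean(optimisms))
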