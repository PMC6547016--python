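"""Discrimination and workload metrics for an early warning score.

All metrics are observation-level: each vital-sign observation set is one
scored unit and its label says whether the admission's adverse event
followed within the look-back window. The headline metric is the AUROC in
its Mann-Whitney form (ties count 1/2): the probability that a randomly
chosen event observation outscores a randomly chosen event-free one. The
confidence interval is a stratified percentile bootstrap that resamples
within each class, preserving the event prevalence exactly in every
replicate. Operating points use the alerting convention score >=
threshold; "efficiency" is the alert fraction of all observations, a
workload proxy. An admission-level summary (max score over the stay vs
the admission outcome) is also provided.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "OperatingPoint",
    "EvaluationReport",
    "auroc",
    "bootstrap_auroc_ci",
    "operating_point",
    "auroc_by_window",
    "efficiency_curve",
    "pr_curve",
    "roc_curve_points",
    "evaluate",
    "admission_level_summary",
    "per_thousand_gains",
    "UndefinedMetricError",
]


class UndefinedMetricError(ValueError):
    """The metric is undefined on this input (e.g. a single-class label set)."""


def _as_arrays(scores: Sequence[float], labels: Sequence[bool]) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-d sequences")
    return s, y


def auroc(scores: Sequence[float], labels: Sequence[bool]) -> float:
    """Area under the ROC curve, Mann-Whitney form with ties counted 1/2."""
    s, y = _as_arrays(scores, labels)
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("AUROC needs both classes present")
    ranks = rankdata(s)  # average ranks handle ties as 1/2
    u = ranks[y].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def bootstrap_auroc_ci(
    scores: Sequence[float],
    labels: Sequence[bool],
    reps: int = 1000,
    seed: int | None = None,
    alpha: float = 0.05,
    batch: int = 64,
) -> tuple[float, float]:
    """Stratified percentile bootstrap CI for the AUROC.

    Each replicate resamples the positives and negatives separately with
    replacement at their original sizes, so the event prevalence is
    preserved exactly. Deterministic under a fixed seed. Replicates are
    ranked in batches for speed.
    """
    s, y = _as_arrays(scores, labels)
    if reps < 2:
        raise ValueError("reps must be >= 2")
    pos = s[y]
    neg = s[~y]
    if pos.size == 0 or neg.size == 0:
        raise UndefinedMetricError("AUROC needs both classes present")
    rng = np.random.default_rng(seed)
    n_pos, n_neg = pos.size, neg.size
    stats = np.empty(reps)
    done = 0
    while done < reps:
        b = min(batch, reps - done)
        ps = pos[rng.integers(0, n_pos, size=(b, n_pos))]
        ns = neg[rng.integers(0, n_neg, size=(b, n_neg))]
        alls = np.concatenate([ps, ns], axis=1)
        ranks = rankdata(alls, axis=1)
        u = ranks[:, :n_pos].sum(axis=1) - n_pos * (n_pos + 1) / 2.0
        stats[done:done + b] = u / (n_pos * n_neg)
        done += b
    low, high = np.quantile(stats, [alpha / 2.0, 1.0 - alpha / 2.0])
    return float(low), float(high)


@dataclass(frozen=True)
class OperatingPoint:
    """Alerting metrics (percent) at an integer score threshold."""

    threshold: int
    sensitivity: float
    specificity: float
    ppv: float | None  # None when no observation alerts at this threshold
    efficiency: float
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0


def operating_point(
    scores: Sequence[float], labels: Sequence[bool], threshold: int
) -> OperatingPoint:
    """Sensitivity/specificity/PPV/efficiency (percent) for alert = score >= threshold."""
    s, y = _as_arrays(scores, labels)
    if y.all() or not y.any():
        raise UndefinedMetricError("operating point needs both classes present")
    alert = s >= threshold
    tp = int((alert & y).sum())
    fp = int((alert & ~y).sum())
    fn = int((~alert & y).sum())
    tn = int((~alert & ~y).sum())
    ppv = None if tp + fp == 0 else 100.0 * tp / (tp + fp)
    return OperatingPoint(
        threshold=int(threshold),
        sensitivity=100.0 * tp / (tp + fn),
        specificity=100.0 * tn / (tn + fp),
        ppv=ppv,
        efficiency=100.0 * (tp + fp) / y.size,
        tp=tp, fp=fp, fn=fn, tn=tn,
    )


def auroc_by_window(
    scores: Sequence[float],
    labels: Sequence[bool],
    time_to_event_h: Sequence[float | None],
    windows: Sequence[float],
) -> list[tuple[float, float | None]]:
    """AUROC as the look-back window shrinks.

    For each window w the positives are event observations with
    time-to-event <= w; the negative set is fixed (all event-free
    observations); event observations outside w are set aside rather than
    relabeled. Windows with no positives yield a missing (None) point.
    Returned in descending window order.
    """
    s, y = _as_arrays(scores, labels)
    tte = np.array([math.nan if t is None else float(t) for t in time_to_event_h])
    if np.isnan(tte[y]).any():
        raise ValueError("every positive needs a time_to_event_h")
    out: list[tuple[float, float | None]] = []
    for w in sorted(windows, reverse=True):
        keep = ~y | (y & (tte <= w))
        yw = y[keep]
        if yw.any() and not yw.all():
            out.append((float(w), auroc(s[keep], yw)))
        else:
            out.append((float(w), None))
    return out


def _threshold_cumulatives(s: np.ndarray, y: np.ndarray):
    """Distinct thresholds (descending) with cumulative alert/event counts."""
    thresholds = np.unique(s)[::-1]
    alerts = (s[None, :] >= thresholds[:, None])  # only used on modest curve inputs
    n_alert = alerts.sum(axis=1)
    n_event_alert = (alerts & y[None, :]).sum(axis=1)
    return thresholds, n_alert, n_event_alert


def efficiency_curve(
    scores: Sequence[float], labels: Sequence[bool]
) -> list[tuple[float, float, float | None]]:
    """Workload curve: one point per distinct score value.

    Each point is (threshold, fraction of all observations at/above it,
    fraction of all event observations at/above it). With no events the
    second coordinate is None for every point (degenerate input).
    """
    s, y = _as_arrays(scores, labels)
    thresholds, n_alert, n_event_alert = _threshold_cumulatives(s, y)
    n = s.size
    n_events = int(y.sum())
    return [
        (float(t), na / n, (nea / n_events) if n_events else None)
        for t, na, nea in zip(thresholds, n_alert, n_event_alert)
    ]


def pr_curve(
    scores: Sequence[float], labels: Sequence[bool]
) -> list[tuple[float, float, float]]:
    """Precision-recall points (threshold, precision, recall), descending threshold."""
    s, y = _as_arrays(scores, labels)
    if not y.any() or y.all():
        raise UndefinedMetricError("precision-recall needs both classes present")
    thresholds, n_alert, n_event_alert = _threshold_cumulatives(s, y)
    n_events = int(y.sum())
    return [
        (float(t), nea / na, nea / n_events)
        for t, na, nea in zip(thresholds, n_alert, n_event_alert)
    ]


def roc_curve_points(
    scores: Sequence[float], labels: Sequence[bool]
) -> list[tuple[float, float, float]]:
    """ROC points (threshold, fpr, tpr), descending threshold; (1,1) reached at min."""
    s, y = _as_arrays(scores, labels)
    if not y.any() or y.all():
        raise UndefinedMetricError("ROC needs both classes present")
    thresholds, n_alert, n_event_alert = _threshold_cumulatives(s, y)
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    return [
        (float(t), (na - nea) / n_neg, nea / n_pos)
        for t, na, nea in zip(thresholds, n_alert, n_event_alert)
    ]


@dataclass
class EvaluationReport:
    """Everything reported for one score variant on one labeled dataset."""

    variant: str
    auroc: float
    ci_low: float
    ci_high: float
    operating_points: list[OperatingPoint]
    roc_curve: list[tuple[float, float, float]]
    pr_curve: list[tuple[float, float, float]]
    efficiency_curve: list[tuple[float, float, float | None]]
    auroc_by_window: list[tuple[float, float | None]]
    n_observations: int
    n_events: int

    def __post_init__(self) -> None:
        if not self.ci_low <= self.auroc <= self.ci_high:
            # percentile intervals can exclude the point estimate only on
            # pathological resamples; treat that as a hard error.
            raise ValueError("confidence interval must bracket the AUROC")


def evaluate(
    scores: Sequence[float],
    labels: Sequence[bool],
    time_to_event_h: Sequence[float | None] | None = None,
    variant: str = "news",
    thresholds: Sequence[int] = (5, 7),
    bootstrap_reps: int = 1000,
    seed: int | None = None,
    windows: Sequence[float] | None = None,
) -> EvaluationReport:
    """Compute the full discrimination/workload report for one score."""
    s, y = _as_arrays(scores, labels)
    point = auroc(s, y)
    lo, hi = bootstrap_auroc_ci(s, y, reps=bootstrap_reps, seed=seed)
    lo, hi = min(lo, point), max(hi, point)
    if time_to_event_h is None:
        time_to_event_h = [None if not lbl else 0.0 for lbl in y]
        window_points: list[tuple[float, float | None]] = []
    else:
        ws = windows if windows is not None else [24, 20, 16, 12, 8, 4, 2, 0]
        window_points = auroc_by_window(s, y, time_to_event_h, ws)
    return EvaluationReport(
        variant=variant,
        auroc=point,
        ci_low=lo,
        ci_high=hi,
        operating_points=[operating_point(s, y, t) for t in thresholds],
        roc_curve=roc_curve_points(s, y),
        pr_curve=pr_curve(s, y),
        efficiency_curve=efficiency_curve(s, y),
        auroc_by_window=window_points,
        n_observations=int(y.size),
        n_events=int(y.sum()),
    )


def admission_level_summary(
    admission_ids: Sequence[str],
    scores: Sequence[float],
    labels: Sequence[bool],
    threshold: int,
) -> dict[str, int]:
    """Admission-level identification at a threshold.

    Aggregation rule: an admission's score is the maximum over its stay,
    and it is an event admission if any of its observations is labeled
    positive. Returns the number of event admissions whose max score
    reaches the threshold ("identified").
    """
    s, y = _as_arrays(scores, labels)
    max_score: dict[str, float] = {}
    any_event: dict[str, bool] = {}
    for aid, sc, lbl in zip(admission_ids, s, y):
        max_score[aid] = max(max_score.get(aid, -math.inf), sc)
        any_event[aid] = any_event.get(aid, False) or bool(lbl)
    event_adm = [a for a, e in any_event.items() if e]
    identified = sum(1 for a in event_adm if max_score[a] >= threshold)
    return {
        "n_admissions": len(max_score),
        "n_event_admissions": len(event_adm),
        "n_identified": identified,
        "threshold": int(threshold),
    }


def per_thousand_gains(
    reference: OperatingPoint, candidate: OperatingPoint
) -> dict[str, float]:
    """Workload-normalised gains of one operating point over another.

    A PPV difference of d percentage points is 10*d extra true alerts per
    1000 alerts; a sensitivity difference of d points is 10*d extra
    detected events per 1000 events.
    """
    if reference.threshold != candidate.threshold:
        raise ValueError("operating points must share a threshold")
    if reference.ppv is None or candidate.ppv is None:
        raise UndefinedMetricError("PPV undefined at this threshold")
    return {
        "extra_true_alerts_per_1000_alerts": 10.0 * (candidate.ppv - reference.ppv),
        "extra_detected_events_per_1000_events":
            10.0 * (candidate.sensitivity - reference.sensitivity),
    }
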