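"""Segment- and event-based seizure-detection metrics.

Segment level: accuracy, sensitivity, specificity and precision from the
confusion counts (reported in percent), plus AUC as the probability that
a positive segment outscores a negative one (Mann-Whitney statistic,
ties counted 1/2).

Event level: a predicted event that overlaps an annotated [onset,
offset) interval detects that seizure (each seizure counted at most
once); detection latency is the time from onset to the first correct
prediction, clamped at 0 when the prediction starts early; predicted
events overlapping no annotation are false alarms, reported per hour of
test recording (FDR).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

__all__ = [
    "ConfusionCounts",
    "EventScore",
    "segment_metrics",
    "auc",
    "event_metrics",
    "average_patient_metrics",
    "pooled_event_metrics",
]


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be nonnegative")
        if self.TP + self.TN + self.FP + self.FN == 0:
            raise ValueError("at least one count must be positive")

    @classmethod
    def from_predictions(cls, y_true: np.ndarray, y_pred: np.ndarray) -> "ConfusionCounts":
        y_true = np.asarray(y_true).astype(bool)
        y_pred = np.asarray(y_pred).astype(bool)
        return cls(
            TP=int((y_true & y_pred).sum()),
            TN=int((~y_true & ~y_pred).sum()),
            FP=int((~y_true & y_pred).sum()),
            FN=int((y_true & ~y_pred).sum()),
        )


def _ratio_pct(num: float, den: float) -> float:
    """Percentage, or NaN when the denominator is empty (undefined)."""
    return 100.0 * num / den if den > 0 else math.nan


def segment_metrics(c: ConfusionCounts) -> dict[str, float]:
    """Accuracy, sensitivity, specificity, precision in percent.

    Metrics with an empty denominator are reported as NaN (undefined),
    never silently as 0.
    """
    return {
        "accuracy": _ratio_pct(c.TN + c.TP, c.TN + c.FP + c.FN + c.TP),
        "sensitivity": _ratio_pct(c.TP, c.TP + c.FN),
        "specificity": _ratio_pct(c.TN, c.TN + c.FP),
        "precision": _ratio_pct(c.TP, c.FP + c.TP),
    }


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Probability that a positive sample outscores a negative one."""
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("AUC requires both classes present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


@dataclass(frozen=True)
class EventScore:
    """Event-level bookkeeping for one test run (typically one patient)."""

    n_test_seizures: int
    n_true_detections: int
    n_false_alarms: int
    test_hours: float
    latencies: tuple[float, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.n_true_detections > self.n_test_seizures:
            raise ValueError("cannot detect more seizures than annotated")
        if not self.test_hours > 0:
            raise ValueError("test_hours must be positive")


def _overlaps(a: tuple[float, float], b: tuple[float, float]) -> bool:
    """Any intersection of half-open intervals [start, end)."""
    return a[0] < b[1] and b[0] < a[1]


def event_metrics(
    predicted: list[tuple[float, float]],
    annotated: list[tuple[float, float]],
    test_hours: float,
) -> tuple[EventScore, dict[str, float]]:
    """Score predicted events against expert annotations.

    A predicted event overlapping an annotation detects that seizure;
    multiple predictions inside one annotation count once (latency from
    the earliest); one prediction spanning two annotations credits both.
    Predictions overlapping no annotation are false alarms.
    """
    for start, end in list(predicted) + list(annotated):
        if end < start:
            raise ValueError(f"negative-duration event ({start}, {end})")
    latencies: list[float] = []
    n_detected = 0
    for onset, offset in annotated:
        hits = [p for p in predicted if _overlaps(p, (onset, offset))]
        if hits:
            n_detected += 1
            first = min(h[0] for h in hits)
            latencies.append(max(0.0, first - onset))
    false_alarms = sum(
        1 for p in predicted if not any(_overlaps(p, a) for a in annotated)
    )
    score = EventScore(
        n_test_seizures=len(annotated),
        n_true_detections=n_detected,
        n_false_alarms=false_alarms,
        test_hours=test_hours,
        latencies=tuple(latencies),
    )
    metrics = {
        "sensitivity": _ratio_pct(n_detected, len(annotated)),
        "fdr_per_hour": false_alarms / test_hours,
        "mean_latency_s": float(np.mean(latencies)) if latencies else math.nan,
    }
    return score, metrics


def average_patient_metrics(per_patient: list[dict[str, float]]) -> dict[str, float]:
    """Equal-weight patient average of metric dicts (NaNs ignored per key)."""
    keys = per_patient[0].keys()
    return {
        k: float(np.nanmean([p[k] for p in per_patient])) for k in keys
    }


def pooled_event_metrics(scores: list[EventScore]) -> dict[str, float]:
    """Pool counts over patients instead of averaging percentages."""
    n_seiz = sum(s.n_test_seizures for s in scores)
    n_det = sum(s.n_true_detections for s in scores)
    n_fa = sum(s.n_false_alarms for s in scores)
    hours = sum(s.test_hours for s in scores)
    lats = [l for s in scores for l in s.latencies]
    return {
        "sensitivity": _ratio_pct(n_det, n_seiz),
        "fdr_per_hour": n_fa / hours if hours > 0 else math.nan,
        "mean_latency_s": float(np.mean(lats)) if lats else math.nan,
    }
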