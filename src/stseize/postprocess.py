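"""Event decisions from per-epoch seizure scores.

Long-term EEG produces a stream of per-epoch (4-s) seizure
probabilities; isolated high scores would otherwise trigger spurious
alarms.  Four stages, in order:

1. moving-average filter (MAF) smooths the score trace,
2. thresholding binarises it,
3. the collar extends every detected run on both sides so true seizure
   boundaries are not clipped,
4. K-of-N discrimination slides an N-epoch window and declares the whole
   window span seizure whenever at least K epochs in it are positive
   (K=5, N=10 i.e. a 40-s window by default).

Contiguous positive runs of the final trace become events with start and
end times in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ScoreTrace",
    "DecisionTrace",
    "PostprocessParams",
    "moving_average",
    "apply_threshold",
    "collar",
    "k_of_n",
    "pipeline",
    "decisions_to_events",
    "events_to_csv",
    "events_from_csv",
    "trace_to_csv",
    "trace_from_csv",
]


@dataclass(frozen=True)
class ScoreTrace:
    """Per-epoch seizure probabilities on a uniform 4-s epoch grid."""

    scores: np.ndarray
    epoch_len: float = 4.0
    start_time: float = 0.0

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=np.float64)
        object.__setattr__(self, "scores", scores)
        if scores.ndim != 1:
            raise ValueError("scores must be 1-D")
        if scores.size and (scores.min() < 0 or scores.max() > 1):
            raise ValueError("scores must lie in [0, 1]")
        if not self.epoch_len > 0:
            raise ValueError("epoch_len must be positive")

    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.scores.size) * self.epoch_len


@dataclass(frozen=True)
class DecisionTrace:
    """Binary per-epoch decisions on the same time base as a ScoreTrace."""

    decisions: np.ndarray
    epoch_len: float = 4.0
    start_time: float = 0.0

    def __post_init__(self) -> None:
        dec = np.asarray(self.decisions)
        if not np.isin(dec, (0, 1)).all():
            raise ValueError("decisions must be 0/1")
        object.__setattr__(self, "decisions", dec.astype(np.int8))


@dataclass(frozen=True)
class PostprocessParams:
    """Stage parameters; MAF window and collar are in epochs."""

    maf_window: int = 3
    threshold: float = 0.5
    collar_epochs: int = 1
    k: int = 5
    n: int = 10


def moving_average(trace: ScoreTrace, w: int) -> ScoreTrace:
    """Centered mean over w epochs, truncated at the trace edges."""
    if w < 1:
        raise ValueError("MAF window must be >= 1")
    if w % 2 == 0:
        raise ValueError("MAF window must be odd (centered)")
    s = trace.scores
    kernel = np.ones(w)
    num = np.convolve(s, kernel, mode="same")
    den = np.convolve(np.ones_like(s), kernel, mode="same")
    return ScoreTrace(num / den, trace.epoch_len, trace.start_time)


def apply_threshold(trace: ScoreTrace, theta: float) -> DecisionTrace:
    """1 where score >= theta, else 0."""
    if not 0 < theta < 1:
        raise ValueError("threshold must be in (0, 1)")
    return DecisionTrace(
        (trace.scores >= theta).astype(np.int8), trace.epoch_len, trace.start_time
    )


def _runs(dec: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of 1s as half-open index intervals [start, stop)."""
    if dec.size == 0:
        return []
    padded = np.concatenate([[0], dec, [0]])
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    stops = np.flatnonzero(d == -1)
    return list(zip(starts, stops))


def collar(dec: DecisionTrace, c: int) -> DecisionTrace:
    """Extend every maximal run of 1s by c epochs on each side."""
    if c < 0:
        raise ValueError("collar width must be >= 0")
    out = dec.decisions.copy()
    n = out.size
    for start, stop in _runs(dec.decisions):
        out[max(0, start - c) : min(n, stop + c)] = 1
    return DecisionTrace(out, dec.epoch_len, dec.start_time)


def k_of_n(dec: DecisionTrace, k: int, n: int) -> DecisionTrace:
    """K-of-N discrimination: mark whole N-epoch spans with >= K positives.

    The window slides one epoch at a time; the output is the union of every
    triggering window's full span.  Windows with fewer than K positives
    contribute nothing, so isolated detections are suppressed.
    """
    length = dec.decisions.size
    if not 1 <= k <= n:
        raise ValueError("require 1 <= K <= N")
    if n > length:
        raise ValueError(f"N={n} exceeds trace length {length}")
    d = dec.decisions.astype(int)
    window_sums = np.convolve(d, np.ones(n, dtype=int), mode="valid")
    out = np.zeros(length, dtype=np.int8)
    for start in np.flatnonzero(window_sums >= k):
        out[start : start + n] = 1
    return DecisionTrace(out, dec.epoch_len, dec.start_time)


def decisions_to_events(dec: DecisionTrace) -> list[tuple[float, float]]:
    """Contiguous 1-runs as (start_s, end_s) half-open intervals."""
    return [
        (
            dec.start_time + start * dec.epoch_len,
            dec.start_time + stop * dec.epoch_len,
        )
        for start, stop in _runs(dec.decisions)
    ]


def pipeline(
    trace: ScoreTrace, params: PostprocessParams | None = None
) -> tuple[DecisionTrace, list[tuple[float, float]]]:
    """MAF -> threshold -> collar -> K-of-N, then extract events."""
    params = params or PostprocessParams()
    smoothed = moving_average(trace, params.maf_window)
    dec = apply_threshold(smoothed, params.threshold)
    dec = collar(dec, params.collar_epochs)
    dec = k_of_n(dec, params.k, params.n)
    return dec, decisions_to_events(dec)


def events_to_csv(events: list[tuple[float, float]], path: str | Path) -> None:
    pd.DataFrame(events, columns=["start_s", "end_s"]).to_csv(path, index=False)


def events_from_csv(path: str | Path) -> list[tuple[float, float]]:
    df = pd.read_csv(path)
    return [(float(r.start_s), float(r.end_s)) for r in df.itertuples()]


def trace_to_csv(trace: ScoreTrace, path: str | Path) -> None:
    pd.DataFrame(
        {"epoch": np.arange(trace.scores.size), "time_s": trace.times(), "score": trace.scores}
    ).to_csv(path, index=False)


def trace_from_csv(path: str | Path, epoch_len: float = 4.0) -> ScoreTrace:
    df = pd.read_csv(path)
    start = float(df["time_s"].iloc[0]) if len(df) else 0.0
    return ScoreTrace(df["score"].to_numpy(), epoch_len, start)
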