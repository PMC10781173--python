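"""Synthetic multichannel scalp EEG with annotated seizures.

Generates recordings that mimic the structure of long-term pediatric
scalp EEG: 23 bipolar 10-20 channels at 256 Hz, amplitudes in the
16-bit microvolt range, long 1/f-weighted interictal background, and
sparse ictal episodes of tens of seconds dominated by rhythmic 3-30 Hz
activity at roughly three times the background amplitude, with slight
per-channel phase and gain variation.  It does NOT attempt physiological
artifacts (eye blinks, EMG) or patient-specific seizure morphologies --
it exists so the full detection pipeline can be exercised and validated
without any external recording.

Segmentation follows the study protocol: 4-s windows, 50% overlap (2-s
stride) inside annotated seizures, no overlap outside them; windows
straddling an annotation boundary are discarded; balanced mode
subsamples the interictal majority to match the ictal count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "EEGRecord",
    "SegmentDataset",
    "SeizureSpec",
    "NoiseSpec",
    "CHB_CHANNELS",
    "generate_record",
    "segment_record",
    "split_train_test",
    "annotations_to_csv",
    "annotations_from_csv",
    "record_to_npz",
    "record_from_npz",
]

# standard 23-channel bipolar longitudinal montage of the CHB-MIT recordings
CHB_CHANNELS: tuple[str, ...] = (
    "FP1-F7", "F7-T7", "T7-P7", "P7-O1",
    "FP1-F3", "F3-C3", "C3-P3", "P3-O1",
    "FP2-F4", "F4-C4", "C4-P4", "P4-O2",
    "FP2-F8", "F8-T8", "T8-P8", "P8-O2",
    "FZ-CZ", "CZ-PZ", "P7-T7", "T7-FT9",
    "FT9-FT10", "FT10-T8", "T8-P8-2",
)

EPOCH_S = 4.0


@dataclass(frozen=True)
class EEGRecord:
    """Continuous multichannel EEG plus seizure annotations.

    ``signal`` is channels x samples in microvolts; ``annotations`` are
    non-overlapping (onset_s, offset_s) half-open intervals.
    """

    signal: np.ndarray
    fs: float
    channel_names: tuple[str, ...]
    annotations: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        signal = np.asarray(self.signal, dtype=np.float64)
        object.__setattr__(self, "signal", signal)
        object.__setattr__(self, "channel_names", tuple(self.channel_names))
        object.__setattr__(
            self, "annotations", tuple((float(a), float(b)) for a, b in self.annotations)
        )
        if signal.ndim != 2:
            raise ValueError("signal must be channels x samples")
        if signal.shape[0] != len(self.channel_names):
            raise ValueError("one name per channel required")
        dur = self.duration_s
        prev_off = -np.inf
        for onset, offset in self.annotations:
            if not offset > onset:
                raise ValueError(f"annotation ({onset}, {offset}) has offset <= onset")
            if onset < 0 or offset > dur:
                raise ValueError(f"annotation ({onset}, {offset}) outside record [0, {dur}]")
            if onset < prev_off:
                raise ValueError("annotations overlap")
            prev_off = offset

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def duration_s(self) -> float:
        return self.signal.shape[1] / self.fs


@dataclass(frozen=True)
class SegmentDataset:
    """Labeled 4-s windows cut from a record."""

    segments: np.ndarray  # (n_segments, n_channels, n_samples)
    labels: np.ndarray  # 0 = interictal, 1 = ictal
    start_times: np.ndarray  # seconds from record start
    fs: float
    channel_names: tuple[str, ...]

    def __post_init__(self) -> None:
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be 0/1")
        if len(self.segments) != len(self.labels) or len(self.labels) != len(self.start_times):
            raise ValueError("segments, labels, start_times must align")

    def __len__(self) -> int:
        return len(self.labels)

    def subset(self, idx: np.ndarray) -> "SegmentDataset":
        return SegmentDataset(
            self.segments[idx], self.labels[idx], self.start_times[idx],
            self.fs, self.channel_names,
        )


@dataclass(frozen=True)
class SeizureSpec:
    """Where and how long the ictal episodes are.

    Either explicit ``times`` or a count with a duration range from which
    episodes are placed at seeded random, non-overlapping, separated by at
    least ``min_gap_s`` of background.
    """

    n_seizures: int = 0
    duration_range_s: tuple[float, float] = (20.0, 90.0)
    min_gap_s: float = 60.0
    times: tuple[tuple[float, float], ...] | None = None
    freq_range_hz: tuple[float, float] = (3.0, 12.0)


@dataclass(frozen=True)
class NoiseSpec:
    """Background and ictal amplitude structure.

    ``background_rms_uv`` sets the interictal RMS per channel;
    ``ictal_amplitude_ratio`` the rhythmic oscillation RMS relative to it;
    ``spectral_exponent`` the 1/f^a power weighting of the background.
    """

    background_rms_uv: float = 30.0
    ictal_amplitude_ratio: float = 3.0
    spectral_exponent: float = 1.0
    phase_jitter_rad: float = 0.3


def _pink_noise(n_channels: int, n_samples: int, fs: float, exponent: float,
                rng: np.random.Generator) -> np.ndarray:
    """Gaussian noise with power spectrum ~ 1/f^exponent, unit RMS rows."""
    white = rng.standard_normal((n_channels, n_samples))
    spec = np.fft.rfft(white, axis=1)
    f = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    weight = np.ones_like(f)
    nz = f > 0
    weight[nz] = np.maximum(f[nz], 1.0) ** (-exponent / 2.0)
    weight[0] = 0.0  # no DC drift
    x = np.fft.irfft(spec * weight, n=n_samples, axis=1)
    rms = x.std(axis=1, keepdims=True)
    return x / rms


def _place_seizures(duration_s: float, spec: SeizureSpec,
                    rng: np.random.Generator) -> list[tuple[float, float]]:
    lo, hi = spec.duration_range_s
    durations = rng.uniform(lo, hi, size=spec.n_seizures)
    total = durations.sum() + spec.min_gap_s * (spec.n_seizures + 1)
    if total > duration_s:
        raise ValueError(
            f"cannot fit {spec.n_seizures} seizures plus gaps into {duration_s} s"
        )
    slack = duration_s - total
    # spread the slack between events via sorted uniform increments
    cuts = np.sort(rng.uniform(0, slack, size=spec.n_seizures))
    extra = np.diff(np.concatenate([[0.0], cuts]))
    events = []
    cursor = 0.0
    for d, e in zip(durations, extra):
        onset = cursor + spec.min_gap_s + e
        events.append((float(onset), float(onset + d)))
        cursor = onset + d
    return events


def generate_record(
    duration_s: float,
    n_channels: int = 23,
    seizures: SeizureSpec | None = None,
    noise: NoiseSpec | None = None,
    seed: int = 0,
) -> EEGRecord:
    """Generate an annotated synthetic EEG record.

    Background is 1/f-weighted Gaussian noise at ``background_rms_uv``;
    each ictal span adds a rhythmic oscillation (random fundamental in
    ``freq_range_hz`` plus a half-amplitude harmonic capped at 30 Hz) with
    per-channel gain and phase jitter and 2-s cosine on/off ramps.
    Bit-reproducible for a fixed seed.
    """
    seizures = seizures or SeizureSpec()
    noise = noise or NoiseSpec()
    fs = 256.0
    n_samples = int(round(duration_s * fs))
    rng = np.random.default_rng(seed)

    if seizures.times is not None:
        events = sorted((float(a), float(b)) for a, b in seizures.times)
    else:
        events = _place_seizures(duration_s, seizures, rng) if seizures.n_seizures else []
    prev_off = -np.inf
    for onset, offset in events:
        if not offset > onset:
            raise ValueError(f"seizure ({onset}, {offset}) has offset <= onset")
        if onset < 0 or offset > duration_s:
            raise ValueError(f"seizure ({onset}, {offset}) outside the record")
        if onset < prev_off:
            raise ValueError("seizures overlap")
        prev_off = offset

    signal = _pink_noise(n_channels, n_samples, fs, noise.spectral_exponent, rng)
    signal *= noise.background_rms_uv

    names = CHB_CHANNELS[:n_channels] if n_channels <= len(CHB_CHANNELS) else tuple(
        f"ch{i}" for i in range(n_channels)
    )
    t = np.arange(n_samples) / fs
    osc_rms = noise.ictal_amplitude_ratio * noise.background_rms_uv
    for onset, offset in events:
        i0, i1 = int(round(onset * fs)), int(round(offset * fs))
        tt = t[i0:i1]
        f0 = rng.uniform(*seizures.freq_range_hz)
        gains = rng.uniform(0.7, 1.3, size=n_channels)
        phases = rng.normal(0.0, noise.phase_jitter_rad, size=n_channels)
        ramp = _on_off_ramp(i1 - i0, fs)
        base = np.sin(2 * np.pi * f0 * tt[None, :] + phases[:, None])
        harm_f = min(2 * f0, 30.0)
        base = base + 0.5 * np.sin(2 * np.pi * harm_f * tt[None, :] + 2 * phases[:, None])
        base_rms = base.std(axis=1, keepdims=True)
        osc = osc_rms * gains[:, None] * base / base_rms
        signal[:, i0:i1] += osc * ramp[None, :]
    return EEGRecord(signal=signal, fs=fs, channel_names=names, annotations=tuple(events))


def _on_off_ramp(n: int, fs: float, ramp_s: float = 2.0) -> np.ndarray:
    """Cosine ramps at both ends so seizures start and end smoothly."""
    ramp_n = min(int(ramp_s * fs), n // 2)
    env = np.ones(n)
    if ramp_n > 0:
        r = 0.5 * (1 - np.cos(np.pi * np.arange(ramp_n) / ramp_n))
        env[:ramp_n] = r
        env[-ramp_n:] = r[::-1]
    return env


def segment_record(rec: EEGRecord, mode: str = "all", seed: int = 0) -> SegmentDataset:
    """Cut a record into labeled 4-s windows per the study protocol.

    Ictal windows: 2-s stride, entirely inside an annotation.  Interictal
    windows: 4-s stride from record start, entirely outside every
    annotation.  ``mode="balanced"`` subsamples interictal windows at
    seeded random to match the ictal count.
    """
    if mode not in ("all", "balanced"):
        raise ValueError(f"unknown mode {mode!r}")
    fs = rec.fs
    win = int(round(EPOCH_S * fs))
    n_samples = rec.signal.shape[1]
    if n_samples < win:
        raise ValueError("record shorter than one 4-s window")

    ictal_starts: list[int] = []
    for onset, offset in rec.annotations:
        i0 = int(round(onset * fs))
        i1 = int(round(offset * fs))
        s = i0
        while s + win <= i1:
            ictal_starts.append(s)
            s += win // 2

    ann_samples = [
        (int(round(a * fs)), int(round(b * fs))) for a, b in rec.annotations
    ]

    def outside(s: int) -> bool:
        return all(s + win <= a or s >= b for a, b in ann_samples)

    inter_starts = [s for s in range(0, n_samples - win + 1, win) if outside(s)]

    import warnings

    if not ictal_starts and rec.annotations:
        warnings.warn("no complete ictal window available", stacklevel=2)
    if not inter_starts:
        warnings.warn("no complete interictal window available", stacklevel=2)

    if mode == "balanced" and len(inter_starts) > len(ictal_starts):
        rng = np.random.default_rng(seed)
        pick = rng.choice(len(inter_starts), size=len(ictal_starts), replace=False)
        inter_starts = [inter_starts[i] for i in np.sort(pick)]

    starts = np.array(ictal_starts + inter_starts, dtype=int)
    labels = np.array([1] * len(ictal_starts) + [0] * len(inter_starts), dtype=int)
    order = np.argsort(starts, kind="stable")
    starts, labels = starts[order], labels[order]
    segments = np.stack([rec.signal[:, s : s + win] for s in starts]) if len(starts) else np.empty((0, rec.n_channels, win))
    return SegmentDataset(
        segments=segments,
        labels=labels,
        start_times=starts / fs,
        fs=fs,
        channel_names=rec.channel_names,
    )


def split_train_test(
    ds: SegmentDataset, ratio: float = 0.75, seed: int = 0
) -> tuple[SegmentDataset, SegmentDataset]:
    """Seeded shuffle then split (default 3:1 train:test)."""
    if not 0 < ratio < 1:
        raise ValueError("ratio must be in (0, 1)")
    n = len(ds)
    if n < 2:
        raise ValueError("dataset too small to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_train = int(round(ratio * n))
    n_train = min(max(n_train, 1), n - 1)
    return ds.subset(order[:n_train]), ds.subset(order[n_train:])


# ---------------------------------------------------------------------------
# persistence


def annotations_to_csv(annotations, path: str | Path) -> None:
    pd.DataFrame(annotations, columns=["onset_s", "offset_s"]).to_csv(path, index=False)


def annotations_from_csv(path: str | Path) -> tuple[tuple[float, float], ...]:
    df = pd.read_csv(path)
    return tuple((float(r.onset_s), float(r.offset_s)) for r in df.itertuples())


def record_to_npz(rec: EEGRecord, path: str | Path) -> None:
    np.savez_compressed(
        path,
        signal=rec.signal,
        fs=rec.fs,
        channel_names=np.array(rec.channel_names),
        annotations=np.array(rec.annotations, dtype=float).reshape(-1, 2),
    )


def record_from_npz(path: str | Path) -> EEGRecord:
    with np.load(path) as data:
        return EEGRecord(
            signal=data["signal"],
            fs=float(data["fs"]),
            channel_names=tuple(str(c) for c in data["channel_names"]),
            annotations=tuple((float(a), float(b)) for a, b in data["annotations"]),
        )
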