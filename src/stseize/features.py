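"""EEG-rhythm sub-band energy features from S-transform matrices.

A 4-s segment's 1-50 Hz time-frequency matrix is compressed into 12
numbers: the six canonical EEG rhythms -- delta (1-4 Hz), theta (4-8),
alpha (8-12), beta (12-30), gamma1 (30-40), gamma2 (40-50) -- each split
into two 2-s time halves, summing |S|^2 over every bin of the unit.
Band boundaries are half-open [low, high) on the integer-Hz row grid, so
e.g. delta covers rows 1-3 and theta rows 4-7.  Stacking channels gives
the n_channels x 12 feature map consumed by the classifier.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .stransform import TFMatrix, stockwell_batch

__all__ = [
    "BandScheme",
    "FeatureMap",
    "FeatureStats",
    "compress_subbands",
    "build_feature_map",
    "normalize_features",
    "feature_maps_to_csv",
    "feature_maps_from_csv",
]

DEFAULT_BANDS: tuple[tuple[str, float, float], ...] = (
    ("delta", 1, 4),
    ("theta", 4, 8),
    ("alpha", 8, 12),
    ("beta", 12, 30),
    ("gamma1", 30, 40),
    ("gamma2", 40, 50),
)


@dataclass(frozen=True)
class BandScheme:
    """Ordered rhythm bands (name, low Hz, high Hz) plus time-block count."""

    bands: tuple[tuple[str, float, float], ...] = DEFAULT_BANDS
    n_time_blocks: int = 2

    def __post_init__(self) -> None:
        if len(self.bands) != 6:
            raise ValueError(f"expected 6 rhythm bands, got {len(self.bands)}")
        if self.n_time_blocks < 1:
            raise ValueError("n_time_blocks must be >= 1")
        for (_, _, hi), (_, lo2, _) in zip(self.bands, self.bands[1:]):
            if hi != lo2:
                raise ValueError("bands must be contiguous and non-overlapping")

    @property
    def fmin(self) -> float:
        return self.bands[0][1]

    @property
    def fmax(self) -> float:
        return self.bands[-1][2]

    @property
    def n_features(self) -> int:
        return len(self.bands) * self.n_time_blocks


@dataclass(frozen=True)
class FeatureMap:
    """Per-segment band-energy matrix, one row per channel, 12 columns."""

    values: np.ndarray  # (n_channels, 12)
    channel_names: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "channel_names", tuple(self.channel_names))
        if values.ndim != 2:
            raise ValueError("feature map must be 2-D")
        if values.shape[0] != len(self.channel_names):
            raise ValueError("one channel name per row required")

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]


def _band_rows(tf_freqs: np.ndarray, scheme: BandScheme) -> list[np.ndarray]:
    """Row indices of each band under the half-open [low, high) convention."""
    rows = []
    for name, lo, hi in scheme.bands:
        sel = np.flatnonzero((tf_freqs >= lo) & (tf_freqs < hi))
        expected = len(np.arange(int(lo), int(hi)))
        if sel.size != expected:
            raise ValueError(
                f"time-frequency matrix does not cover band {name} "
                f"[{lo}, {hi}) Hz: found {sel.size} of {expected} rows"
            )
        rows.append(sel)
    return rows


def compress_subbands(tf: TFMatrix, scheme: BandScheme | None = None) -> np.ndarray:
    """Compress one channel's S-transform into the 12-value energy vector.

    Output is band-major: (delta, first half), (delta, second half),
    (theta, first half), ...  Each value is the sum of |S|^2 over the
    unit's frequency rows and time columns.
    """
    scheme = scheme or BandScheme()
    band_rows = _band_rows(tf.freqs, scheme)
    n_cols = tf.values.shape[1]
    if n_cols % scheme.n_time_blocks != 0:
        raise ValueError(
            f"column count {n_cols} not divisible by {scheme.n_time_blocks} time blocks"
        )
    block = n_cols // scheme.n_time_blocks
    power = tf.power
    out = np.empty(scheme.n_features)
    i = 0
    for rows in band_rows:
        band_power = power[rows]
        for b in range(scheme.n_time_blocks):
            out[i] = band_power[:, b * block : (b + 1) * block].sum()
            i += 1
    return out


def build_feature_map(
    signals: np.ndarray,
    fs: float,
    scheme: BandScheme | None = None,
    channel_names: tuple[str, ...] | None = None,
) -> FeatureMap:
    """Assemble the n_channels x 12 feature map of a multichannel segment.

    Parameters
    ----------
    signals : ndarray, shape (n_channels, n_samples)
        One 4-s segment, all channels at the same sampling rate.
    fs : sampling rate in Hz.
    """
    scheme = scheme or BandScheme()
    signals = np.asarray(signals, dtype=np.float64)
    if signals.ndim != 2:
        raise ValueError("segment must be 2-D (n_channels, n_samples); ragged input?")
    n_ch = signals.shape[0]
    if channel_names is None:
        channel_names = tuple(f"ch{c}" for c in range(n_ch))
    if len(channel_names) != n_ch:
        raise ValueError("channel_names length must match channel count")
    st = stockwell_batch(signals, fs, scheme.fmin, scheme.fmax)
    freqs = np.arange(int(scheme.fmin), int(scheme.fmax) + 1, dtype=float)
    times = np.arange(signals.shape[1]) / fs
    rows = [
        compress_subbands(TFMatrix(values=st[c], freqs=freqs, times=times), scheme)
        for c in range(n_ch)
    ]
    return FeatureMap(values=np.vstack(rows), channel_names=channel_names)


@dataclass(frozen=True)
class FeatureStats:
    """Per-feature z-scoring statistics fitted on a training set."""

    mean: np.ndarray  # (12,)
    scale: np.ndarray  # (12,)


def normalize_features(
    maps: list[FeatureMap],
    stats: FeatureStats | None = None,
    mode: str = "zscore",
) -> tuple[list[FeatureMap], FeatureStats | None]:
    """Z-score the 12 feature columns across all segments and channels.

    With ``stats=None`` the statistics are fitted on ``maps`` and returned
    for reuse on held-out data; with fitted ``stats`` the same affine
    transform is applied.  ``mode="identity"`` returns the input unchanged.
    Zero-variance features get their scale clamped to 1 with a warning.
    """
    if mode == "identity":
        return maps, stats
    if mode != "zscore":
        raise ValueError(f"unknown normalization mode {mode!r}")
    if stats is None:
        stacked = np.vstack([m.values for m in maps])
        mean = stacked.mean(axis=0)
        scale = stacked.std(axis=0)
        zero = scale == 0
        if zero.any():
            warnings.warn(
                f"{int(zero.sum())} zero-variance feature(s); scale clamped to 1",
                stacklevel=2,
            )
            scale = np.where(zero, 1.0, scale)
        stats = FeatureStats(mean=mean, scale=scale)
    else:
        if stats.mean.shape != (maps[0].values.shape[1],):
            raise ValueError("stats dimensions do not match feature width")
    out = [
        FeatureMap(
            values=(m.values - stats.mean) / stats.scale,
            channel_names=m.channel_names,
        )
        for m in maps
    ]
    return out, stats


def feature_maps_to_csv(
    maps: list[FeatureMap],
    labels: np.ndarray,
    path: str | Path,
    segment_times: np.ndarray | None = None,
) -> None:
    """Write feature maps to CSV, one row per segment-channel."""
    records = []
    labels = np.asarray(labels)
    for i, m in enumerate(maps):
        for c, name in enumerate(m.channel_names):
            rec = {"segment_id": i, "channel": name, "label": int(labels[i])}
            if segment_times is not None:
                rec["start_s"] = float(segment_times[i])
            rec.update({f"f{j:02d}": m.values[c, j] for j in range(m.values.shape[1])})
            records.append(rec)
    pd.DataFrame.from_records(records).to_csv(path, index=False)


def feature_maps_from_csv(path: str | Path) -> tuple[list[FeatureMap], np.ndarray, np.ndarray | None]:
    """Read feature maps written by :func:`feature_maps_to_csv`.

    Returns (maps, labels, segment start times or None).
    """
    df = pd.read_csv(path)
    feat_cols = sorted(c for c in df.columns if c.startswith("f") and c[1:].isdigit())
    maps: list[FeatureMap] = []
    labels: list[int] = []
    times: list[float] = []
    has_times = "start_s" in df.columns
    for _, grp in df.groupby("segment_id", sort=True):
        maps.append(
            FeatureMap(
                values=grp[feat_cols].to_numpy(),
                channel_names=tuple(grp["channel"].astype(str)),
            )
        )
        labels.append(int(grp["label"].iloc[0]))
        if has_times:
            times.append(float(grp["start_s"].iloc[0]))
    return maps, np.asarray(labels), (np.asarray(times) if has_times else None)
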