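"""EDF reading/writing and annotation sidecars.

Recordings travel as 16-bit EDF (the format of long-term scalp-EEG
archives) with seizure annotations in a sidecar CSV of (onset_s,
offset_s) rows -- mirroring how such datasets ship a summary file next
to each recording rather than embedded EDF+ annotations.

Reading goes through :mod:`mne`; writing uses a small self-contained
EDF encoder (ASCII header + int16 data records) sufficient for the
synthetic records produced here: uniform sampling rate, 1-s data
records, whole-second durations.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np

from .synthdata import EEGRecord, annotations_from_csv

__all__ = ["read_edf", "write_edf", "annotation_sidecar_path"]


def annotation_sidecar_path(edf_path: str | Path) -> Path:
    """`rec.edf` -> `rec_annotations.csv` in the same directory."""
    p = Path(edf_path)
    return p.with_name(p.stem + "_annotations.csv")


def _ascii(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def _phys_extremum(m: float) -> float:
    """Smallest value >= m whose repr fits the 7 chars left of a signed field."""
    for prec in range(6, 0, -1):
        s = f"{m:.{prec}g}"
        if len(s) <= 7 and float(s) >= m:
            return float(s)
        s = f"{m * (1 + 10.0 ** (1 - prec)):.{prec}g}"
        if len(s) <= 7 and float(s) >= m:
            return float(s)
    raise ValueError(f"cannot represent physical extremum {m} in an EDF field")


def write_edf(rec: EEGRecord, path: str | Path, annotations_csv: bool = True) -> None:
    """Write a record as 16-bit EDF (1-s data records).

    Physical scaling is per channel, symmetric around zero, so round-trip
    error is bounded by half a quantisation step.  The duration is
    truncated to whole seconds.  Annotations go to the sidecar CSV.
    """
    path = Path(path)
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    spr = int(round(fs))  # samples per 1-s record per channel
    n_records = rec.signal.shape[1] // spr
    if n_records * spr != rec.signal.shape[1]:
        warnings.warn("duration truncated to whole seconds for EDF", stacklevel=2)
    nch = rec.n_channels
    data = rec.signal[:, : n_records * spr]

    # the header stores physical extrema as ASCII (8 chars incl. sign); scale
    # with exactly the value the reader will parse back
    phys_max = np.array(
        [_phys_extremum(m) for m in np.maximum(np.abs(data).max(axis=1), 1e-6)]
    )
    dig_max, dig_min = 32767, -32768
    # readers decode as phys = cal*(dig - dig_min) + phys_min with
    # cal = (phys_max - phys_min)/(dig_max - dig_min) = cal*(dig + 1/2) here,
    # so encode accordingly; quantisation error is then bounded by cal/2
    cal = 2 * phys_max / (dig_max - dig_min)

    header = b"".join(
        [
            _ascii("0", 8),  # version
            _ascii("X X X X", 80),  # patient id (anonymous)
            _ascii("Startdate X X X X", 80),  # recording id
            _ascii("01.01.00", 8),  # start date
            _ascii("00.00.00", 8),  # start time
            _ascii(256 + nch * 256, 8),  # header bytes
            _ascii("", 44),  # reserved
            _ascii(n_records, 8),
            _ascii(1, 8),  # record duration (s)
            _ascii(nch, 4),
        ]
    )
    fields = [
        b"".join(_ascii(name, 16) for name in rec.channel_names),
        b"".join(_ascii("EEG", 80) for _ in range(nch)),  # transducer
        b"".join(_ascii("uV", 8) for _ in range(nch)),
        b"".join(_ascii(f"{-m:.6g}"[:8], 8) for m in phys_max),  # phys min
        b"".join(_ascii(f"{m:.6g}"[:8], 8) for m in phys_max),  # phys max
        b"".join(_ascii(dig_min, 8) for _ in range(nch)),
        b"".join(_ascii(dig_max, 8) for _ in range(nch)),
        b"".join(_ascii("", 80) for _ in range(nch)),  # prefilter
        b"".join(_ascii(spr, 8) for _ in range(nch)),
        b"".join(_ascii("", 32) for _ in range(nch)),  # reserved
    ]
    digital = np.clip(
        np.round(data / cal[:, None] - 0.5), dig_min, dig_max
    ).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(header)
        for f in fields:
            fh.write(f)
        # data records: per record, channel-major blocks of spr samples
        for r in range(n_records):
            fh.write(digital[:, r * spr : (r + 1) * spr].tobytes())
    if annotations_csv:
        from .synthdata import annotations_to_csv

        annotations_to_csv(rec.annotations, annotation_sidecar_path(path))


def read_edf(
    path: str | Path,
    channels: tuple[str, ...] | None = None,
    expected_fs: float = 256.0,
    resample: bool = False,
    annotations: str | Path | None = "auto",
) -> EEGRecord:
    """Load an EDF file (and sidecar annotations) into an EEGRecord.

    Parameters
    ----------
    channels : optional subset of channel names, loaded in the given order.
    expected_fs : target sampling rate; a mismatch raises unless
        ``resample`` is set, in which case the signal is polyphase-resampled.
    annotations : path to the (onset_s, offset_s) CSV; ``"auto"`` looks for
        the sidecar next to the EDF; ``None`` skips annotations.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"EDF file not found: {path}")
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    fs = float(raw.info["sfreq"])
    data = raw.get_data() * 1e6  # volts -> microvolts
    names = tuple(raw.ch_names)
    if channels is not None:
        idx = []
        for ch in channels:
            if ch not in names:
                raise ValueError(f"channel {ch!r} not in file ({names})")
            idx.append(names.index(ch))
        data = data[idx]
        names = tuple(channels)
    if abs(fs - expected_fs) > 1e-6:
        if not resample:
            raise ValueError(
                f"sampling rate {fs} Hz != expected {expected_fs} Hz "
                "(pass resample=True to convert)"
            )
        from scipy.signal import resample_poly
        from fractions import Fraction

        frac = Fraction(int(round(expected_fs * 1000)), int(round(fs * 1000)))
        data = resample_poly(data, frac.numerator, frac.denominator, axis=1)
        fs = expected_fs
    ann: tuple[tuple[float, float], ...] = ()
    if annotations == "auto":
        sidecar = annotation_sidecar_path(path)
        if sidecar.exists():
            ann = annotations_from_csv(sidecar)
    elif annotations is not None:
        ann = annotations_from_csv(annotations)
    return EEGRecord(signal=data, fs=fs, channel_names=names, annotations=ann)
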