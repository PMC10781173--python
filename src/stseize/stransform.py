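"""Discrete Stockwell transform (S-transform) of EEG segments.

The S-transform is a time-frequency representation that slides a
frequency-scaled Gaussian window over the signal while retaining the
absolute phase reference of the Fourier transform:

    S(tau, f) = sum_t  x[t] * (f / sqrt(2*pi)) * exp(-(tau - t)^2 f^2 / 2)
                      * exp(-i 2 pi f t)

with t and tau in seconds on the sample grid.  Low frequencies get a wide
window (good frequency resolution), high frequencies a narrow one (good
time localisation), which suits rhythmic ictal EEG activity.

Two implementations are exposed:

* :func:`stockwell_direct` -- literal evaluation of the sum above; slow,
  serves as the brute-force oracle.
* :func:`stockwell_fft` -- frequency-domain evaluation (one FFT per
  frequency voice, vectorised); identical contract, used everywhere else.

Both use circular (periodic) edge handling: the Gaussian window is
periodised over the segment length, so the two forms agree to machine
precision.  The frequency grid is one row per integer Hz; a 4-s,
1024-point segment at 256 Hz analysed over 1-128 Hz therefore yields a
128 x 1024 complex matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SignalSegment",
    "TFMatrix",
    "stockwell_direct",
    "stockwell_fft",
    "stockwell_batch",
]

_MIN_SEGMENT_LEN = 8


@dataclass(frozen=True)
class SignalSegment:
    """A single-channel signal segment in microvolts.

    Attributes
    ----------
    samples : ndarray, shape (n,)
        Signal values (microvolts).
    fs : float
        Sampling rate in Hz.
    """

    samples: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        object.__setattr__(self, "samples", samples)
        if samples.ndim != 1:
            raise ValueError(f"segment must be 1-D, got shape {samples.shape}")
        if samples.size < _MIN_SEGMENT_LEN:
            raise ValueError(
                f"segment too short: {samples.size} < {_MIN_SEGMENT_LEN} samples"
            )
        if not np.isfinite(samples).all():
            raise ValueError("segment contains non-finite samples")
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")

    @property
    def n(self) -> int:
        return self.samples.size


@dataclass(frozen=True)
class TFMatrix:
    """Complex S-transform matrix, frequency rows by time columns."""

    values: np.ndarray  # complex, (n_freqs, n_times)
    freqs: np.ndarray  # Hz, strictly increasing
    times: np.ndarray  # seconds

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.complex128)
        freqs = np.asarray(self.freqs, dtype=np.float64)
        times = np.asarray(self.times, dtype=np.float64)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "freqs", freqs)
        object.__setattr__(self, "times", times)
        if values.shape != (freqs.size, times.size):
            raise ValueError(
                f"shape mismatch: values {values.shape} vs "
                f"{freqs.size} freqs x {times.size} times"
            )
        if freqs.size > 1 and not np.all(np.diff(freqs) > 0):
            raise ValueError("frequency rows must be strictly increasing")

    @property
    def power(self) -> np.ndarray:
        """Squared modulus |S|^2."""
        return np.abs(self.values) ** 2


def _validate_band(fs: float, fmin: float, fmax: float) -> np.ndarray:
    if not 1 <= fmin <= fmax:
        raise ValueError(f"need 1 <= fmin <= fmax, got fmin={fmin}, fmax={fmax}")
    if fmax > fs / 2:
        raise ValueError(
            f"fmax={fmax} Hz violates the Nyquist limit fs/2 = {fs / 2} Hz"
        )
    return np.arange(int(np.ceil(fmin)), int(np.floor(fmax)) + 1, dtype=np.float64)


def _periodised_window(f: float, n: int, fs: float) -> np.ndarray:
    """Sampled Gaussian voice window, periodised over the segment length.

    w[j] = (f/sqrt(2 pi)) * sum_p exp(-((j + p*n)/fs)^2 * f^2 / 2)

    The wrap count is chosen so truncated tails are below double precision.
    """
    dt = 1.0 / fs
    period = n * dt
    # tails decay like exp(-(p*period*f)^2/2); p*period*f > 10 is ~1e-22
    n_wraps = int(np.ceil(10.0 / (period * f))) + 1
    j = np.arange(n, dtype=np.float64)
    w = np.zeros(n)
    for p in range(-n_wraps, n_wraps + 1):
        t = (j + p * n) * dt
        w += np.exp(-0.5 * (t * f) ** 2)
    return w * (f / np.sqrt(2.0 * np.pi))


def _window_spectrum(freqs: np.ndarray, n: int, fs: float) -> np.ndarray:
    """Exact DFT of the periodised sampled Gaussian window, one row per voice.

    By Poisson summation the DFT of a sampled, periodised Gaussian equals the
    aliased samples of its continuous Fourier transform:

        G[m] = fs * sum_q exp(-2 pi^2 (nu_m - q*fs)^2 / f^2)

    with nu_m the signed DFT bin frequencies.  |q| <= 2 covers aliasing far
    below double precision for f <= fs/2.
    """
    nu = np.fft.fftfreq(n, d=1.0 / fs)  # Hz, signed
    f_col = freqs[:, None]
    g = np.zeros((freqs.size, n))
    for q in (-2, -1, 0, 1, 2):
        g += np.exp(-2.0 * np.pi**2 * (nu[None, :] - q * fs) ** 2 / f_col**2)
    return fs * g


def stockwell_direct(seg: SignalSegment, fmin: float, fmax: float) -> TFMatrix:
    """Brute-force S-transform: evaluate the defining sum row by row.

    One row per integer frequency in [fmin, fmax]; every sample index is a
    time column.  O(n^2) per row -- use :func:`stockwell_fft` for anything
    beyond oracle-sized inputs.
    """
    freqs = _validate_band(seg.fs, fmin, fmax)
    n = seg.n
    dt = 1.0 / seg.fs
    t = np.arange(n) * dt
    # circulant index (tau - t) mod n
    idx = (np.arange(n)[:, None] - np.arange(n)[None, :]) % n
    values = np.empty((freqs.size, n), dtype=np.complex128)
    for r, f in enumerate(freqs):
        w = _periodised_window(f, n, seg.fs)
        u = seg.samples * np.exp(-2j * np.pi * f * t)
        values[r] = w[idx] @ u
    return TFMatrix(values=values, freqs=freqs, times=t)


def stockwell_fft(seg: SignalSegment, fmin: float, fmax: float) -> TFMatrix:
    """FFT-accelerated S-transform, identical contract to the direct form.

    Each voice is a circular convolution of the demodulated signal with the
    Gaussian window, evaluated in the frequency domain.  When a requested
    frequency falls on an integer DFT bin the demodulation reduces to a
    spectrum shift and a single signal FFT serves all rows.
    """
    freqs = _validate_band(seg.fs, fmin, fmax)
    values = _stockwell_rows(seg.samples[None, :], seg.fs, freqs)[0]
    times = np.arange(seg.n) / seg.fs
    return TFMatrix(values=values, freqs=freqs, times=times)


def stockwell_batch(signals: np.ndarray, fs: float, fmin: float, fmax: float) -> np.ndarray:
    """S-transform of a batch of equal-length signals.

    Parameters
    ----------
    signals : ndarray, shape (n_signals, n_samples)
    fs : sampling rate in Hz.

    Returns
    -------
    ndarray, complex, shape (n_signals, n_freqs, n_samples)
        One integer-Hz row per frequency in [fmin, fmax].
    """
    signals = np.asarray(signals, dtype=np.float64)
    if signals.ndim != 2:
        raise ValueError("signals must be 2-D (n_signals, n_samples)")
    if not np.isfinite(signals).all():
        raise ValueError("signals contain non-finite samples")
    freqs = _validate_band(fs, fmin, fmax)
    return _stockwell_rows(signals, fs, freqs)


def _stockwell_rows(x: np.ndarray, fs: float, freqs: np.ndarray) -> np.ndarray:
    """Compute S-transform rows for batched signals x of shape (B, n)."""
    n = x.shape[-1]
    g = _window_spectrum(freqs, n, fs)  # (F, n)
    bins = freqs * n / fs
    if np.allclose(bins, np.round(bins), atol=1e-9):
        # integer-bin fast path: demodulation == spectrum shift
        k = np.round(bins).astype(int)
        X = np.fft.fft(x, axis=-1)  # (B, n)
        shift_idx = (np.arange(n)[None, :] + k[:, None]) % n  # (F, n)
        U = X[:, shift_idx]  # (B, F, n)
    else:
        dt = 1.0 / fs
        t = np.arange(n) * dt
        phase = np.exp(-2j * np.pi * freqs[:, None] * t[None, :])  # (F, n)
        U = np.fft.fft(x[:, None, :] * phase[None, :, :], axis=-1)
    return np.fft.ifft(U * g[None, :, :], axis=-1)
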