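"""Spectral relative-energy features from a single-channel EEG trace.

The feature pipeline is: segment the raw trace into fixed-length windows,
take the squared-magnitude DFT spectrum of each window (the power spectral
density), sum the spectrum over the four clinical frequency bands
(delta 0.5-3 Hz, theta 4-7 Hz, alpha 8-13 Hz, beta 14-30 Hz), and divide
each band energy by the four-band total.  The resulting relative energies
(RE) are scale-free, which removes inter-subject amplitude differences.
Classifier inputs ("patterns") are concatenations of ``n`` consecutive RE
vectors, so a pattern carries 4*n values and describes a short stretch of
the recent signal ending at the decision time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "BANDS",
    "BAND_ORDER",
    "RawSignal",
    "PsdSpectrum",
    "segment_signal",
    "compute_psd",
    "band_energies",
    "relative_energies",
    "window_relative_energies",
    "build_patterns",
    "read_signal_csv",
    "write_patterns_csv",
]

#: Closed band edges in Hz.  Bins falling in the inter-band gaps
#: (3-4, 7-8, 13-14 Hz exclusive) belong to no band and are dropped.
BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.5, 3.0),
    "theta": (4.0, 7.0),
    "alpha": (8.0, 13.0),
    "beta": (14.0, 30.0),
}

BAND_ORDER: tuple[str, ...] = ("delta", "theta", "alpha", "beta")


@dataclass
class RawSignal:
    """A single-channel EEG trace in microvolts.

    Parameters
    ----------
    samples : ndarray
        Voltage samples, one per time step.
    fs : float
        Sampling rate in Hz (default 500).
    """

    samples: np.ndarray
    fs: float = 500.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if self.samples.size == 0:
            raise ValueError("signal must contain at least one sample")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    def __len__(self) -> int:
        return self.samples.size


@dataclass
class PsdSpectrum:
    """One-sided squared-magnitude spectrum of a window, DC excluded.

    ``values[j]`` is the power at DFT bin ``i = j + 1`` whose frequency is
    ``fs * i / T``; bins run ``i = 1 .. T/2``.
    """

    values: np.ndarray
    fs: float
    T: int
    freqs: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size != self.T // 2:
            raise ValueError("spectrum must hold T/2 bins (DC excluded)")
        self.freqs = self.fs * np.arange(1, self.T // 2 + 1) / self.T


def segment_signal(raw: RawSignal, T: int = 1000, stride: int | None = None) -> np.ndarray:
    """Cut a trace into fixed-length windows, oldest first.

    Windows start at offsets ``0, stride, 2*stride, ...``; a trailing
    stretch shorter than ``T`` is discarded.  The default stride equals the
    window length, i.e. non-overlapping 2 s windows at 500 Hz.

    Returns
    -------
    ndarray of shape (n_windows, T)
    """
    if stride is None:
        stride = T
    if T < 2:
        raise ValueError("window length T must be at least 2 samples")
    if stride < 1:
        raise ValueError("stride must be at least 1 sample")
    n = len(raw)
    if n < T:
        raise ValueError(
            f"signal has {n} samples but at least {T} are required for one window"
        )
    count = (n - T) // stride + 1
    starts = np.arange(count) * stride
    return np.stack([raw.samples[s : s + T] for s in starts])


def compute_psd(window: np.ndarray, fs: float = 500.0) -> PsdSpectrum:
    """Squared-magnitude DFT spectrum of one window, bins ``1 .. T/2``.

    The DC bin is excluded; it belongs to no band.
    """
    window = np.asarray(window, dtype=float).ravel()
    T = window.size
    if T < 2:
        raise ValueError("window must contain at least 2 samples")
    coeffs = np.fft.rfft(window)
    # rfft yields bins 0 .. T//2; drop DC, keep 1 .. T//2
    values = np.abs(coeffs[1 : T // 2 + 1]) ** 2
    return PsdSpectrum(values=values, fs=fs, T=T)


def band_energies(psd: PsdSpectrum) -> dict[str, float]:
    """Sum spectrum power over each clinical band (closed intervals).

    Bins in the 3-4, 7-8 and 13-14 Hz gaps contribute to no band.
    """
    out: dict[str, float] = {}
    for name in BAND_ORDER:
        lo, hi = BANDS[name]
        mask = (psd.freqs >= lo) & (psd.freqs <= hi)
        out[name] = float(psd.values[mask].sum())
    return out


def relative_energies(energies: dict[str, float]) -> np.ndarray:
    """Normalize band energies to the four-band total.

    Returns the RE vector in band order (delta, theta, alpha, beta); the
    components sum to one.  All-zero energies leave the ratio undefined.
    """
    e = np.array([energies[name] for name in BAND_ORDER], dtype=float)
    if np.any(e < 0):
        raise ValueError("band energies must be non-negative")
    total = e.sum()
    if total <= 0:
        raise ValueError("all band energies are zero; relative energy undefined")
    return e / total


def window_relative_energies(
    raw: RawSignal, T: int = 1000, stride: int | None = None
) -> np.ndarray:
    """RE vectors for every window of a trace, shape (n_windows, 4)."""
    windows = segment_signal(raw, T=T, stride=stride)
    out = np.empty((windows.shape[0], 4))
    for i, w in enumerate(windows):
        out[i] = relative_energies(band_energies(compute_psd(w, fs=raw.fs)))
    return out


def build_patterns(
    res: np.ndarray, n: int, labels: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray | None]:
    """Concatenate ``n`` consecutive RE vectors into 4*n-value patterns.

    A sliding window of stride 1 over the RE sequence yields
    ``len(res) - n + 1`` patterns.  A pattern inherits the label of its
    last window — the time the drowsiness decision refers to.

    Parameters
    ----------
    res : ndarray of shape (m, 4)
        Per-window RE vectors, oldest first.
    n : int
        Pattern length (number of windows per pattern).
    labels : ndarray of shape (m,), optional
        Per-window labels (1 = drowsy, 0 = non-drowsy).

    Returns
    -------
    (patterns, pattern_labels)
        ``patterns`` has shape (m - n + 1, 4 * n), band-major within each
        window and oldest window first; ``pattern_labels`` is None when no
        labels were given.
    """
    res = np.asarray(res, dtype=float)
    if res.ndim != 2 or res.shape[1] != 4:
        raise ValueError("res must be an (m, 4) array of RE vectors")
    if n < 1:
        raise ValueError("pattern length n must be at least 1")
    m = res.shape[0]
    if m < n:
        raise ValueError(f"need at least {n} RE vectors, got {m}")
    count = m - n + 1
    patterns = np.stack([res[i : i + n].ravel() for i in range(count)])
    if labels is None:
        return patterns, None
    labels = np.asarray(labels)
    if labels.shape[0] != m:
        raise ValueError("labels must match the number of RE vectors")
    return patterns, labels[n - 1 :]


def read_signal_csv(path, fs: float = 500.0) -> RawSignal:
    """Read a raw EEG trace from CSV: one microvolt sample per row.

    A single non-numeric header line is tolerated.
    """
    try:
        values = pd.read_csv(path, header=None).iloc[:, 0]
        samples = pd.to_numeric(values, errors="raise").to_numpy()
    except (ValueError, TypeError):
        samples = pd.read_csv(path).iloc[:, 0].to_numpy(dtype=float)
    return RawSignal(samples=samples, fs=fs)


def write_patterns_csv(path, patterns: np.ndarray, labels: np.ndarray | None = None) -> None:
    """Write patterns as CSV: 4n feature columns plus an optional label column.

    Columns are named ``w{k}_{band}`` for window slot k (oldest first).
    """
    n = patterns.shape[1] // 4
    cols = [f"w{k}_{band}" for k in range(n) for band in BAND_ORDER]
    df = pd.DataFrame(patterns, columns=cols)
    if labels is not None:
        df["label"] = labels
    df.to_csv(path, index=False)
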