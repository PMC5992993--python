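"""Band-pass filtering, average reference, global field power, GFP peaks.

The global field power (GFP) is the per-sample standard deviation of the
potential across electrodes (population form, divisor n_ch).  Its strict
local maxima mark the moments of highest topographic signal-to-noise and
are the samples fed into microstate clustering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .eeg_io import EEGRecord

__all__ = [
    "GFPSeries",
    "bandpass_filter",
    "average_reference",
    "gfp",
    "find_gfp_peaks",
    "peaks_per_second",
]

_FILTER_ORDER = 4  # Butterworth, applied forward-backward (zero phase)


@dataclass
class GFPSeries:
    """GFP values plus the indices of their strict local maxima."""

    values: np.ndarray
    peak_indices: np.ndarray

    @classmethod
    def from_data(cls, data: np.ndarray) -> "GFPSeries":
        g = gfp(data)
        return cls(values=g, peak_indices=find_gfp_peaks(g))


def bandpass_filter(record: EEGRecord, f_lo: float, f_hi: float) -> EEGRecord:
    """Zero-phase Butterworth band-pass of every channel.

    Forward-backward filtering cancels the group delay so that topography
    timing (hence GFP peak locations) is preserved.  Requires
    0 < f_lo < f_hi < fs/2.
    """
    nyq = record.fs / 2.0
    if not (0 < f_lo < f_hi):
        raise ValueError(f"need 0 < f_lo < f_hi, got ({f_lo}, {f_hi})")
    if f_hi >= nyq:
        raise ValueError(f"upper band edge {f_hi} Hz >= Nyquist {nyq} Hz")
    sos = butter(_FILTER_ORDER, [f_lo, f_hi], btype="bandpass", fs=record.fs,
                 output="sos")
    filtered = sosfiltfilt(sos, record.data, axis=0)
    return EEGRecord(data=filtered, fs=record.fs,
                     channel_names=list(record.channel_names),
                     layout=record.layout)


def average_reference(data: np.ndarray) -> np.ndarray:
    """Re-reference to the common average: zero mean across channels per sample."""
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[1] < 2:
        raise ValueError("data must be (n_t, n_ch) with n_ch >= 2")
    return data - data.mean(axis=1, keepdims=True)


def gfp(data: np.ndarray) -> np.ndarray:
    """Global field power: per-sample population std across channels."""
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[1] < 2:
        raise ValueError("data must be (n_t, n_ch) with n_ch >= 2")
    return data.std(axis=1, ddof=0)


def find_gfp_peaks(g: np.ndarray) -> np.ndarray:
    """Indices of strict local maxima of a 1-D series.

    Endpoints are never peaks.  A flat run that is higher than both of its
    distinct neighbours counts once, at its first index.
    """
    g = np.asarray(g, dtype=float).ravel()
    if g.size < 3:
        raise ValueError("need at least 3 samples to define a local maximum")
    change = np.flatnonzero(np.diff(g) != 0)
    starts = np.concatenate(([0], change + 1))   # first index of each flat run
    vals = g[starts]
    if vals.size < 3:
        return np.array([], dtype=int)
    interior = np.flatnonzero((vals[1:-1] > vals[:-2]) & (vals[1:-1] > vals[2:])) + 1
    return starts[interior]


def peaks_per_second(peaks: np.ndarray, n_t: int, fs: float) -> float:
    """Mean GFP-peak rate in peaks per second."""
    if n_t <= 0:
        raise ValueError("n_t must be positive")
    return len(peaks) * fs / n_t
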