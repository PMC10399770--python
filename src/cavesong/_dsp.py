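"""Shared signal-processing primitives (band-pass filtering, envelopes)."""

from __future__ import annotations

import numpy as np
from scipy.signal import butter, hilbert, sosfiltfilt

#: Analysis band (Hz) — the widest bandwidth spanned by the click sounds.
BAND_LOW = 500.0
BAND_HIGH = 10_000.0


def band_pass(x: np.ndarray, sample_rate: float,
              low: float = BAND_LOW, high: float = BAND_HIGH,
              order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth band-pass restricted to the analysis band."""
    nyq = sample_rate / 2.0
    high = min(high, 0.99 * nyq)
    if low >= high:
        raise ValueError(f"invalid band [{low}, {high}] at fs={sample_rate}")
    sos = butter(order, [low / nyq, high / nyq], btype="band", output="sos")
    return sosfiltfilt(sos, x)


def moving_average(x: np.ndarray, width: int) -> np.ndarray:
    """Centered moving average with edge truncation (same length as input)."""
    if width <= 1:
        return np.asarray(x, dtype=float)
    kernel = np.ones(width) / width
    # normalize edges so a constant input stays constant
    num = np.convolve(x, kernel, mode="same")
    den = np.convolve(np.ones_like(x, dtype=float), kernel, mode="same")
    return num / den


def envelope(x: np.ndarray, sample_rate: float,
             smoothing: float = 0.0005) -> np.ndarray:
    """Amplitude envelope: magnitude of the analytic signal, smoothed by a
    centered moving average of ``smoothing`` seconds (0 disables smoothing)."""
    if smoothing < 0:
        raise ValueError("smoothing must be >= 0")
    env = np.abs(hilbert(np.asarray(x, dtype=float)))
    width = int(round(smoothing * sample_rate))
    return moving_average(env, width)
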