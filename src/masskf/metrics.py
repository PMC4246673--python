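"""Accuracy metrics for state tracking and parameter recovery."""

from __future__ import annotations

import numpy as np
from scipy.signal import welch


def percent_bias(estimate, truth):
    """Absolute terminal estimation error as a percentage of the truth."""
    estimate = np.asarray(estimate, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if np.any(truth == 0):
        raise ZeroDivisionError("percent bias undefined for zero truth")
    out = 100.0 * np.abs(estimate - truth) / np.abs(truth)
    return out if out.ndim else float(out)


def rms_final_second(estimated: np.ndarray, true: np.ndarray,
                     delta: float) -> float:
    """RMS tracking error over the final second of two aligned traces."""
    estimated = np.asarray(estimated, dtype=float)
    true = np.asarray(true, dtype=float)
    if estimated.shape != true.shape:
        raise ValueError("traces must be aligned and equally long")
    n = int(round(1.0 / delta))
    if len(estimated) < n:
        raise ValueError("traces must cover at least one second")
    diff = estimated[-n:] - true[-n:]
    return float(np.sqrt(np.mean(diff**2)))


def spectral_peak(signal: np.ndarray, sample_rate: float,
                  band: tuple[float, float] = (1.0, 45.0)) -> float:
    """Frequency (Hz) of the maximum of an averaged periodogram in ``band``.

    Welch segments of 4 s (or the whole signal if shorter) give ~0.25 Hz
    resolution; requires at least 10 s of signal.
    """
    signal = np.asarray(signal, dtype=float)
    if len(signal) < 10 * sample_rate:
        raise ValueError("need at least 10 s of signal")
    nperseg = int(min(4 * sample_rate, len(signal)))
    freqs, power = welch(signal - signal.mean(), fs=sample_rate,
                         nperseg=nperseg)
    mask = (freqs >= band[0]) & (freqs <= band[1])
    return float(freqs[mask][np.argmax(power[mask])])
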