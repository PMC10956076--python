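"""Excitation/inhibition indices.

Two estimators of cortical E/I balance from EEG:

* the model-based ratio ``mE/I = A / (A + B)`` computed per sample from
  the filter-estimated excitatory and inhibitory synaptic gains;
* the spectral-slope baseline: the slope of the log-log power spectral
  density between 30 and 50 Hz (more negative = more
  inhibition-dominant), provided for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .vbcenkf import FilterResult

__all__ = ["EISeries", "mei_ratio", "mei_series", "ei_slope", "sliding_ei_slope"]


@dataclass
class EISeries:
    """A time-indexed E/I index with its method tag."""

    t: np.ndarray
    value: np.ndarray
    method: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t": self.t, "value": self.value, "method": self.method})

    def __len__(self) -> int:
        return self.t.size


def mei_ratio(A, B):
    """Model-based E/I ratio A / (A + B).

    Strictly in (0, 1) for positive gains; scale-invariant, increasing
    in A and decreasing in B.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    total = A + B
    if np.any(total == 0):
        raise ZeroDivisionError("A + B must be nonzero")
    out = A / total
    return float(out) if out.ndim == 0 else out


def mei_series(result: FilterResult) -> EISeries:
    """Per-sample mE/I ratio from a filter run's estimated gains."""
    return EISeries(
        t=result.t, value=mei_ratio(result.A_hat, result.B_hat), method="mei"
    )


def ei_slope(
    eeg,
    fs: float,
    band: tuple[float, float] = (30.0, 50.0),
    nperseg: int | None = None,
) -> float:
    """Spectral E/I slope: OLS slope of log10 PSD vs log10 frequency.

    The PSD is a Welch estimate (2-s Hann windows, 50% overlap by
    default) and the fit uses every bin whose center frequency lies in
    the closed ``band``.  The upper band edge must not exceed the
    Nyquist frequency: a 100 Hz recording supports the default 30-50 Hz
    band exactly, and anything above is refused rather than silently
    truncated.
    """
    lo, hi = band
    if not 0 < lo < hi:
        raise ValueError("band must satisfy 0 < lo < hi")
    if hi > fs / 2:
        raise ValueError(
            f"band upper edge {hi} Hz exceeds the Nyquist frequency {fs / 2} Hz"
        )
    x = np.asarray(eeg, dtype=float)
    if nperseg is None:
        nperseg = int(round(2 * fs))
    if x.size < nperseg:
        raise ValueError("series shorter than one PSD window")
    freqs, psd = signal.welch(
        x, fs=fs, window="hann", nperseg=nperseg, noverlap=nperseg // 2
    )
    mask = (freqs >= lo) & (freqs <= hi) & (psd > 0)
    if mask.sum() < 2:
        raise ValueError("fewer than two PSD bins inside the band")
    slope = np.polyfit(np.log10(freqs[mask]), np.log10(psd[mask]), 1)[0]
    return float(slope)


def sliding_ei_slope(
    eeg,
    fs: float,
    window_s: float = 30.0,
    band: tuple[float, float] = (30.0, 50.0),
) -> EISeries:
    """Time-resolved E/I slope over non-overlapping windows.

    The 30-s default matches standard sleep-scoring epoch length, so the
    slope series aligns with hypnogram epochs.
    """
    x = np.asarray(eeg, dtype=float)
    step = int(round(window_s * fs))
    if step <= 0 or x.size < step:
        raise ValueError("series shorter than one window")
    starts = np.arange(0, x.size - step + 1, step)
    values = np.array([ei_slope(x[s : s + step], fs, band) for s in starts])
    t = (starts + step / 2.0) / fs
    return EISeries(t=t, value=values, method="slope")
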