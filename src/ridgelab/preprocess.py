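"""Signal conditioning: robust outlier removal, notch and bandpass filtering.

All filters are applied forward-backward (zero phase) so that downstream
ridge-phase estimates do not inherit filter phase distortion.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import signal

from .io import Recording

__all__ = ["notch_filter", "butterworth_bandpass", "huber_x84_clean", "X84_K"]

#: X84 rejection rule: samples more than 5.2 median absolute deviations from
#: the channel median are outliers (~3 sigma for Gaussian data).
X84_K = 5.2


def notch_filter(rec: Recording, base_freq: float = 50.0, n_harmonics: int = 1,
                 q: float = 30.0) -> Recording:
    """Suppress power-line interference at ``base_freq`` and its harmonics.

    One IIR band-stop of quality factor ``q`` per harmonic, applied with
    zero phase.  Harmonics at or above Nyquist are skipped.
    """
    nyq = rec.fs / 2
    if base_freq >= nyq:
        raise ValueError(f"base_freq {base_freq} Hz is at or above Nyquist ({nyq} Hz)")
    out = rec.samples.copy()
    for h in range(1, n_harmonics + 1):
        f0 = base_freq * h
        if f0 >= nyq:
            break
        b, a = signal.iirnotch(f0, q, fs=rec.fs)
        out = signal.filtfilt(b, a, out, axis=-1)
    return rec.copy_with(out)


def butterworth_bandpass(rec: Recording, low: float = 2.0, high: float = 10.0,
                         order: int = 4) -> Recording:
    """Zero-phase Butterworth bandpass (default 2-10 Hz, order 4)."""
    nyq = rec.fs / 2
    if not (0 < low < high < nyq):
        raise ValueError(f"need 0 < low < high < Nyquist, got [{low}, {high}] at fs={rec.fs}")
    if order < 1:
        raise ValueError("order must be >= 1")
    sos = signal.butter(order, [low, high], btype="bandpass", fs=rec.fs, output="sos")
    return rec.copy_with(signal.sosfiltfilt(sos, rec.samples, axis=-1))


def _x84_clean_channel(x: np.ndarray) -> np.ndarray:
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    bad = np.abs(x - med) > X84_K * mad
    if not bad.any():
        return x
    if mad == 0:
        warnings.warn(
            "degenerate channel (MAD = 0 with deviating samples); passed through unchanged",
            RuntimeWarning,
        )
        return x
    y = x.copy()
    idx = np.arange(x.size)
    good = idx[~bad]
    # linear interpolation from nearest inliers; np.interp clamps at the ends
    y[bad] = np.interp(idx[bad], good, x[good])
    return y


def huber_x84_clean(rec: Recording) -> Recording:
    """Replace X84 outliers (|x - median| > 5.2 MAD) by linear interpolation.

    Interpolation rather than deletion keeps the time axis intact for the
    wavelet transform.  Idempotent in the sense that a second pass finds the
    replaced samples inside the inlier band.
    """
    if rec.n_times < 16:
        raise ValueError("need at least 16 samples per channel for robust statistics")
    return rec.copy_with(np.vstack([_x84_clean_channel(ch) for ch in rec.samples]))
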