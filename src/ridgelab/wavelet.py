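"""Morlet continuous wavelet spectrograms and ridge extraction.

The ridge of the wavelet spectrogram -- the per-time absolute maximum of the
modulus over frequency -- carries the instantaneous amplitude, frequency and
phase of a slowly amplitude-modulated oscillation (stationary-phase result).
The complex Morlet mother wavelet

    psi(t) = (pi*fb)**-0.5 * exp(-t**2/fb) * exp(2j*pi*fc*t)

is analysed on a *linear frequency grid*: the scale for analysis frequency f
is a = fc/f, and the transform is evaluated in the Fourier domain through
the exact transfer function

    H_a(f') = exp(-pi**2 * fb * (a*f' - fc)**2),

normalized so that the ridge modulus of a real tone equals its envelope
amplitude (negative frequencies are suppressed by H itself, making the
output analytic).  This normalization keeps the ridge of a pure tone at the
tone frequency with no scale-dependent bias.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.fft import fft, ifft, next_fast_len

__all__ = [
    "WaveletSpec",
    "Spectrogram",
    "Ridge",
    "morlet_cwt",
    "extract_ridge",
    "ridge_from_signal",
    "ridge_phase_direct",
    "ridge_phase_fm",
    "validity_mask",
    "wrap_phase",
]

#: seconds of edge contamination at analysis frequency f: 2/f
COI_CYCLES = 2.0


@dataclass(frozen=True)
class WaveletSpec:
    """Morlet parameters and analysis grid.

    fb, fc : dimensionless Morlet bandwidth and center frequency (default 1).
    fmin, fmax : analysis band in Hz.
    df : linear frequency grid step in Hz; must be much finer than any
        ridge-frequency comparison tolerance used downstream (default 0.05).
    """

    fb: float = 1.0
    fc: float = 1.0
    fmin: float = 0.5
    fmax: float = 22.0
    df: float = 0.05

    def __post_init__(self) -> None:
        if self.fb <= 0 or self.fc <= 0:
            raise ValueError("fb and fc must be positive")
        if not (0 < self.fmin < self.fmax):
            raise ValueError("need 0 < fmin < fmax")
        if self.df <= 0:
            raise ValueError("df must be positive")

    @property
    def freqs(self) -> np.ndarray:
        n = int(round((self.fmax - self.fmin) / self.df)) + 1
        return self.fmin + self.df * np.arange(n)

    @property
    def scales(self) -> np.ndarray:
        return self.fc / self.freqs


@dataclass
class Spectrogram:
    """Complex Morlet CWT on a frequency x time grid for one channel."""

    coeffs: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    channel: str = ""
    df: float = field(default=0.05)

    def __post_init__(self) -> None:
        if self.coeffs.shape != (self.freqs.size, self.times.size):
            raise ValueError("coefficient matrix does not match the grids")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("frequency grid must be strictly increasing")

    @property
    def modulus(self) -> np.ndarray:
        return np.abs(self.coeffs)

    def coi_mask(self) -> np.ndarray:
        """Boolean (freq x time) mask, True where edge-contaminated."""
        span = COI_CYCLES / self.freqs[:, None]
        t0, t1 = self.times[0], self.times[-1]
        return (self.times[None, :] - t0 < span) | (t1 - self.times[None, :] < span)


@dataclass
class Ridge:
    """Per-sample ridge of a wavelet spectrogram for one channel.

    fr is the ridge frequency (Hz), modulus the spectrogram modulus at the
    ridge, psd the modulus squared per unit bandwidth (uV^2/Hz), phase in
    (-pi, pi], and valid a per-sample quality flag (edges and
    stationary-phase violations are flagged out).
    """

    times: np.ndarray
    fr: np.ndarray
    modulus: np.ndarray
    psd: np.ndarray
    phase: np.ndarray
    valid: np.ndarray
    channel: str = ""
    coeff_at_ridge: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = self.times.size
        for name in ("fr", "modulus", "psd", "phase", "valid"):
            if getattr(self, name).size != n:
                raise ValueError(f"ridge array {name!r} length mismatch")

    @property
    def fs(self) -> float:
        return 1.0 / float(np.median(np.diff(self.times)))


def wrap_phase(phi: np.ndarray) -> np.ndarray:
    """Wrap angles to (-pi, pi]."""
    out = np.angle(np.exp(1j * np.asarray(phi, dtype=float)))
    # np.angle returns [-pi, pi); move the branch point so -pi maps to +pi
    out = np.where(out == -np.pi, np.pi, out)
    return out


def _prepare_fft(x: np.ndarray, fs: float, fmin: float) -> tuple[np.ndarray, np.ndarray, int]:
    n = x.size
    pad = int(np.ceil(4.0 / fmin * fs))  # room for the widest kernel's tails
    nfft = next_fast_len(n + 2 * pad)
    xf = fft(x, nfft)
    fft_freqs = np.fft.fftfreq(nfft, d=1.0 / fs)
    return xf, fft_freqs, nfft


def _cwt_rows(xf: np.ndarray, fft_freqs: np.ndarray, nfft: int, n: int,
              freqs: np.ndarray, fb: float, fc: float) -> np.ndarray:
    """CWT coefficients for a block of analysis frequencies (rows)."""
    scales = fc / freqs
    h = np.exp(-np.pi**2 * fb * (scales[:, None] * fft_freqs[None, :] - fc) ** 2)
    # factor 2: report the envelope of a real signal, analytic-signal style
    return 2.0 * ifft(xf[None, :] * h, axis=1)[:, :n]


def morlet_cwt(x: np.ndarray, fs: float, spec: WaveletSpec | None = None,
               channel: str = "", t0: float = 0.0) -> Spectrogram:
    """Morlet CWT of a single channel on a linear frequency grid.

    Raises if the band reaches Nyquist or the record is shorter than two
    cycles of the lowest analysis frequency.
    """
    spec = spec or WaveletSpec()
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("morlet_cwt expects a single channel")
    if spec.fmax >= fs / 2:
        raise ValueError(f"fmax {spec.fmax} Hz is at or above Nyquist ({fs/2} Hz)")
    if x.size < 2.0 / spec.fmin * fs:
        raise ValueError("record shorter than 2 cycles of fmin")
    xf, fft_freqs, nfft = _prepare_fft(x, fs, spec.fmin)
    coeffs = _cwt_rows(xf, fft_freqs, nfft, x.size, spec.freqs, spec.fb, spec.fc)
    times = t0 + np.arange(x.size) / fs
    return Spectrogram(coeffs, spec.freqs, times, channel, spec.df)


def _coi_valid(times: np.ndarray, fr: np.ndarray) -> np.ndarray:
    span = COI_CYCLES / fr
    return (times - times[0] >= span) & (times[-1] - times >= span)


def extract_ridge(sg: Spectrogram) -> Ridge:
    """Ridge as the per-time frequency argmax of the spectrogram modulus.

    Ties are broken toward the lower frequency; samples inside the cone of
    influence at their own ridge frequency are flagged invalid.
    """
    if sg.coeffs.size == 0:
        raise ValueError("empty spectrogram")
    m = sg.modulus
    idx = m.argmax(axis=0)  # argmax returns the first (lowest-frequency) tie
    cols = np.arange(m.shape[1])
    modulus = m[idx, cols]
    coeff = sg.coeffs[idx, cols]
    fr = sg.freqs[idx]
    return Ridge(
        times=sg.times,
        fr=fr,
        modulus=modulus,
        psd=modulus**2 / sg.df,
        phase=np.zeros_like(fr),
        valid=_coi_valid(sg.times, fr),
        channel=sg.channel,
        coeff_at_ridge=coeff,
    )


def ridge_from_signal(x: np.ndarray, fs: float, spec: WaveletSpec | None = None,
                      channel: str = "", t0: float = 0.0,
                      block: int = 48) -> Ridge:
    """Ridge of a channel without materializing the full spectrogram.

    Streams the frequency grid in blocks, keeping only the running maximum
    modulus, its frequency and its complex coefficient.  Identical to
    ``extract_ridge(morlet_cwt(...))`` but with O(block x n) memory, which is
    what makes multi-hour records tractable.
    """
    spec = spec or WaveletSpec()
    x = np.asarray(x, dtype=float)
    if spec.fmax >= fs / 2:
        raise ValueError(f"fmax {spec.fmax} Hz is at or above Nyquist ({fs/2} Hz)")
    if x.size < 2.0 / spec.fmin * fs:
        raise ValueError("record shorter than 2 cycles of fmin")
    xf, fft_freqs, nfft = _prepare_fft(x, fs, spec.fmin)
    freqs = spec.freqs
    n = x.size
    best_mod = np.full(n, -1.0)
    best_fr = np.full(n, freqs[0])
    best_coeff = np.zeros(n, dtype=complex)
    for lo in range(0, freqs.size, block):
        fchunk = freqs[lo : lo + block]
        w = _cwt_rows(xf, fft_freqs, nfft, n, fchunk, spec.fb, spec.fc)
        m = np.abs(w)
        j = m.argmax(axis=0)
        cols = np.arange(n)
        mj = m[j, cols]
        upd = mj > best_mod  # strict: earlier (lower) frequency wins ties
        best_mod[upd] = mj[upd]
        best_fr[upd] = fchunk[j[upd]]
        best_coeff[upd] = w[j[upd], cols[upd]]
    times = t0 + np.arange(n) / fs
    return Ridge(
        times=times,
        fr=best_fr,
        modulus=best_mod,
        psd=best_mod**2 / spec.df,
        phase=np.zeros(n),
        valid=_coi_valid(times, best_fr),
        channel=channel,
        coeff_at_ridge=best_coeff,
    )


def ridge_phase_direct(sg_or_ridge: Spectrogram | Ridge, ridge: Ridge | None = None) -> Ridge:
    """Ridge phase as the four-quadrant angle of W at (t, fr).

    Accepts either a spectrogram plus its ridge, or a ridge that already
    carries the complex coefficient at the ridge.  Zero coefficients get
    phase 0 and are flagged invalid.
    """
    if isinstance(sg_or_ridge, Spectrogram):
        if ridge is None:
            raise ValueError("pass the ridge extracted from this spectrogram")
        sg = sg_or_ridge
        idx = np.searchsorted(sg.freqs, ridge.fr)
        idx = np.clip(idx, 0, sg.freqs.size - 1)
        coeff = sg.coeffs[idx, np.arange(sg.times.size)]
        ridge = replace(ridge, coeff_at_ridge=coeff)
    else:
        ridge = sg_or_ridge
        if ridge.coeff_at_ridge is None:
            raise ValueError("ridge carries no coefficients; extract it from a spectrogram")
        coeff = ridge.coeff_at_ridge
    zero = coeff == 0
    phase = np.where(zero, 0.0, np.angle(coeff))
    phase = np.where(phase == -np.pi, np.pi, phase)
    return replace(ridge, phase=phase, valid=ridge.valid & ~zero)


def ridge_phase_fm(ridge: Ridge) -> Ridge:
    """Frequency-modulation phase 2*pi*fr(t)*t, wrapped to (-pi, pi].

    Treats the ridge as a frequency-modulated oscillation whose phase is
    read directly off the instantaneous ridge frequency; for interchannel
    phase differences this reduces to comparing ridge-frequency tracks.
    """
    return replace(ridge, phase=wrap_phase(2 * np.pi * ridge.fr * ridge.times))


def validity_mask(ridge: Ridge, tol: float = 0.1) -> Ridge:
    """Flag samples violating the stationary-phase condition |fr'|/(2 fr^2) << 1.

    ``tol`` quantifies "much less than one" (default 0.1, an order below).
    The cone of influence is already excluded by ridge extraction; this adds
    the slow-modulation requirement.
    """
    dfr = np.gradient(ridge.fr, ridge.times)
    crit = np.abs(dfr) / (2.0 * ridge.fr**2)
    return replace(ridge, valid=ridge.valid & (crit < tol))
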