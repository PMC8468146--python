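"""Synthetic EEG-like test signals with known ground truth.

Clinical EEG of the kind the ridge methods target is not publicly
shareable, so every analysis stage is exercised on generated surrogates
that reproduce the structural features the methods measure: narrowband
oscillations with drifting frequency, periodic spike-wave trains, slow
rhythmic broadband chewing-like bursts, 1/f background noise with an alpha
component, and channel pairs with planted phase locking.  All generators
are deterministic given their seed, and planted episodes are emitted as the
same interval format the segmentation pipeline outputs, so recovered and
planted intervals can be scored directly against each other.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import Interval, IntervalSet, Recording

__all__ = [
    "FMSignalSpec",
    "Episode",
    "PlantedRecordSpec",
    "CHANNELS_1020",
    "gen_fm",
    "gen_tone",
    "gen_chirp",
    "gen_spike_wave",
    "gen_chew_bursts",
    "gen_locked_pair",
    "gen_background",
    "gen_monitoring_record",
    "gen_connectivity_records",
]

#: 19 scalp electrodes of the 10-20 placement system.
CHANNELS_1020 = [
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T3", "C3", "Cz", "C4", "T4",
    "T5", "P3", "Pz", "P4", "T6", "O1", "O2",
]


@dataclass(frozen=True)
class FMSignalSpec:
    """Frequency-modulated oscillation x = A0 sin(2*pi Int f(t) dt + phase0).

    The instantaneous frequency is f(t) = f_center + f_dev * xi(t) with the
    modulator xi in [-1, 1]: "const" (xi = 0, a pure tone), "linear" (a
    chirp sweeping f_center +/- f_dev), "sin" (sinusoidal FM at 0.1 Hz), or
    "randomwalk" (smoothed random drift, the EEG-like default for planted
    oscillators).
    """

    A0: float = 50.0          # microvolts
    f_center: float = 6.0     # Hz
    f_dev: float = 0.0        # Hz
    modulator: str = "const"
    phase0: float = 0.0       # radians

    def __post_init__(self) -> None:
        if self.A0 <= 0:
            raise ValueError("amplitude must be positive")
        if self.f_center - self.f_dev <= 0:
            raise ValueError("instantaneous frequency must stay positive")


def _modulator(name: str, t: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    if name == "const":
        return np.zeros_like(t)
    if name == "linear":
        return -1.0 + 2.0 * t / t[-1] if t.size > 1 else np.zeros_like(t)
    if name == "sin":
        return np.sin(2 * np.pi * 0.1 * t)
    if name == "randomwalk":
        # smoothed random walk clipped to [-1, 1]; correlation time ~2 s
        fs = 1.0 / (t[1] - t[0])
        steps = rng.standard_normal(t.size) / np.sqrt(fs)
        walk = np.cumsum(steps)
        k = int(2 * fs)
        kernel = np.hanning(max(3, k))
        kernel /= kernel.sum()
        walk = np.convolve(np.pad(walk, len(kernel) // 2, mode="edge"), kernel,
                           mode="valid")[: t.size]
        return np.clip(walk / 3.0, -1.0, 1.0)
    raise ValueError(f"unknown modulator {name!r}")


def gen_fm(spec: FMSignalSpec, fs: float, duration: float,
           seed: int | np.random.Generator = 0) -> tuple[np.ndarray, np.ndarray]:
    """Sampled FM signal and its ground-truth instantaneous frequency."""
    if spec.f_center + spec.f_dev >= fs / 2:
        raise ValueError("instantaneous frequency reaches Nyquist")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    t = np.arange(int(round(duration * fs))) / fs
    f_inst = spec.f_center + spec.f_dev * _modulator(spec.modulator, t, rng)
    # exclusive cumulative sum: the phase at sample 0 is exactly phase0
    phase = spec.phase0 + 2 * np.pi * (np.cumsum(f_inst) - f_inst) / fs
    return spec.A0 * np.sin(phase), f_inst


def gen_tone(f0: float, fs: float, duration: float, amplitude: float = 50.0,
             phase0: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    """Pure sinusoid of frequency f0 (the f_dev = 0 limit of gen_fm)."""
    return gen_fm(FMSignalSpec(amplitude, f0, 0.0, "const", phase0), fs, duration)


def gen_chirp(f_start: float, f_end: float, fs: float, duration: float,
              amplitude: float = 50.0) -> tuple[np.ndarray, np.ndarray]:
    """Linear chirp from f_start to f_end with its known frequency law."""
    if min(f_start, f_end) <= 0 or max(f_start, f_end) >= fs / 2:
        raise ValueError("chirp frequencies must stay in (0, Nyquist)")
    n = int(round(duration * fs))
    f_inst = np.linspace(f_start, f_end, n)
    phase = 2 * np.pi * (np.cumsum(f_inst) - f_inst) / fs
    return amplitude * np.sin(phase), f_inst


def _spike_wave_complex(fs: float, spike_amp: float, wave_amp: float) -> np.ndarray:
    """One biphasic spike (70 ms) followed by a slow half-sine wave (250 ms)."""
    n_spike = int(round(0.070 * fs))
    ts = np.arange(n_spike) / n_spike
    spike = spike_amp * np.sin(2 * np.pi * ts) * np.hanning(n_spike)
    n_wave = int(round(0.250 * fs))
    wave = wave_amp * np.sin(np.pi * np.arange(n_wave) / n_wave)
    return np.concatenate([spike, wave])


def _event_times(rate: float, duration: float, jitter: float,
                 rng: np.random.Generator, t0: float = 0.0) -> np.ndarray:
    """Event times of a renewal train: periods drawn N(1/rate, jitter).

    Period (not phase) jitter accumulates from event to event, so a jittered
    train genuinely loses long-range rhythm stability and its repetition
    line in a spectrum broadens, instead of merely losing power into a flat
    floor as independently displaced events would.
    """
    times = []
    t = t0
    while t < duration:
        times.append(t)
        period = 1.0 / rate + (rng.normal(0.0, jitter) if jitter > 0 else 0.0)
        t += max(period, 0.2 / rate)
    return np.asarray(times)


def gen_spike_wave(rate: float, fs: float, duration: float, jitter: float = 0.0,
                   spike_amp: float = 200.0, wave_amp: float = 100.0,
                   alternation: float = 0.1,
                   seed: int | np.random.Generator = 0) -> np.ndarray:
    """Periodic spike-wave train: an epileptic-discharge surrogate.

    Complexes repeat at ``rate`` Hz with optional Gaussian period jitter
    (seconds, cumulative).  The 70 ms spike puts broadband energy well above
    4 Hz, so a 4 Hz spectrogram slice pulses once per complex.
    ``alternation`` makes consecutive complexes alternate in amplitude by
    +/- that fraction, the waxing-waning prominence of real spike-wave runs;
    it places a second, subharmonic peak at rate/2 in the slice spectrum
    (a time-resolution-limited stand-in for the multi-peak structure of
    clinical spike-wave slice spectra).
    """
    if not (0.3 <= rate <= 4.0):
        raise ValueError("repetition rate must lie in [0.3, 4] Hz")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = int(round(duration * fs))
    x = np.zeros(n)
    complex_ = _spike_wave_complex(fs, spike_amp, wave_amp)
    for k, t_event in enumerate(_event_times(rate, duration, jitter, rng)):
        gain = 1.0 + alternation * (1 if k % 2 == 0 else -1)
        i0 = int(round(t_event * fs))
        seg = complex_[: n - i0]
        x[i0 : i0 + seg.size] += gain * seg
    return x


def gen_chew_bursts(rate: float = 0.71, fs: float = 256.0, duration: float = 60.0,
                    jitter: float = 0.25, amplitude: float = 150.0,
                    burst_freq: float = 5.0, burst_sd: float = 0.12,
                    seed: int | np.random.Generator = 0) -> np.ndarray:
    """Slow rhythmic broadband bursts: a chewing-artifact surrogate.

    Each chew is a Gaussian-enveloped oscillatory burst (default 5 Hz
    carrier, 120 ms envelope sd) repeating at ``rate`` Hz.  Chewing is a
    voluntary rhythm, far less stable than a discharge, so its period
    jitter defaults to 0.25 s (~18% of the period); the cumulative jitter
    broadens the repetition line, which is what makes the chewing FWHM
    larger than the discharge FWHM.  Pass ``jitter=0`` for a strictly
    periodic train.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    x = np.zeros(n)
    half = 4 * burst_sd
    for t_event in _event_times(rate, duration + half, jitter, rng, t0=0.5 / rate):
        sel = (t >= t_event - half) & (t < t_event + half)
        tau = t[sel] - t_event
        x[sel] += amplitude * np.exp(-(tau**2) / (2 * burst_sd**2)) * np.cos(
            2 * np.pi * burst_freq * tau
        )
    return x


def gen_locked_pair(base: FMSignalSpec, kappa: float, fs: float, duration: float,
                    seed: int | np.random.Generator = 0,
                    anchor_period: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Two channels sharing a ridge-frequency track with von Mises phase locking.

    The second channel's phase offset follows a slowly varying process whose
    anchors (one per ``anchor_period`` seconds, smoothly interpolated) are
    drawn von Mises(0, kappa): large kappa keeps the offset near zero and
    both ridge tracks identical; kappa = 0 lets the offset wander the full
    circle, i.e. independent phases.  Returns the (2, n) signal array and
    the shared ground-truth frequency track.
    """
    if kappa < 0:
        raise ValueError("concentration kappa must be >= 0")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    x1, f_track = gen_fm(base, fs, duration, rng)
    n = x1.size
    t = np.arange(n) / fs
    n_anchor = max(2, int(np.ceil(duration / anchor_period)) + 1)
    anchors = rng.vonmises(0.0, kappa, size=n_anchor)
    # interpolate the offset on the unwrapped circle to avoid 2*pi jumps
    anchors = np.unwrap(anchors)
    t_anchor = np.linspace(0, duration, n_anchor)
    offset = np.interp(t, t_anchor, anchors)
    phase = base.phase0 + 2 * np.pi * (np.cumsum(f_track) - f_track) / fs
    x2 = base.A0 * np.sin(phase + offset)
    return np.vstack([x1, x2]), f_track


def gen_background(n_channels: int, fs: float, duration: float,
                   seed: int | np.random.Generator = 0,
                   pink_rms: float = 10.0, alpha_amp: float = 5.0,
                   rhythm_amp: float = 0.0) -> np.ndarray:
    """Resting-EEG-like background: 1/f noise plus a 10 Hz alpha component.

    With ``rhythm_amp`` > 0 each channel additionally carries its own
    dominant rhythm at a channel-specific frequency (spread over the
    theta-to-beta range, 4.5-18 Hz, with slight drift; an awake resting
    background keeps its dominant rhythms above the delta band, which
    belongs to the pathological events planted on top).  Pure 1/f noise pins every channel's spectrogram
    ridge at the bottom of the analysis band, which would make all channel
    pairs trivially "synchronized"; distinct dominant rhythms keep the
    background ridges apart, the way different montage sites carry
    different rhythms.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = int(round(duration * fs))
    freqs = np.fft.rfftfreq(n, 1 / fs)
    shape = np.zeros_like(freqs)
    shape[1:] = 1.0 / np.sqrt(freqs[1:])
    out = np.empty((n_channels, n))
    t = np.arange(n) / fs
    centers = np.linspace(4.5, 18.0, max(n_channels, 2))[rng.permutation(max(n_channels, 2))]
    for c in range(n_channels):
        white = rng.standard_normal(n)
        pink = np.fft.irfft(np.fft.rfft(white) * shape, n)
        pink *= pink_rms / pink.std()
        alpha_phase = 2 * np.pi * 10.0 * t + np.cumsum(
            rng.standard_normal(n)
        ) * 0.3 / np.sqrt(fs)
        out[c] = pink + alpha_amp * np.sin(alpha_phase + rng.uniform(0, 2 * np.pi))
        if rhythm_amp > 0:
            spec = FMSignalSpec(rhythm_amp, float(centers[c]), 0.15, "randomwalk")
            out[c] += gen_fm(spec, fs, duration, rng)[0]
    return out


@dataclass(frozen=True)
class Episode:
    """One planted event: where, when, what kind, with what parameters."""

    start: float
    end: float
    kind: str                         # sync_tone | spike_wave | chew_burst | locked_pair
    channels: tuple[str, ...]
    params: dict = field(default_factory=dict)


@dataclass
class PlantedRecordSpec:
    """Recipe for a synthetic monitoring record with ground truth."""

    n_channels: int = 19
    fs: float = 256.0
    duration: float = 1800.0
    episodes: list[Episode] = field(default_factory=list)
    seed: int = 0
    pink_rms: float = 10.0
    alpha_amp: float = 5.0
    rhythm_amp: float = 20.0
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        if self.labels is None:
            if self.n_channels <= len(CHANNELS_1020):
                self.labels = CHANNELS_1020[: self.n_channels]
            else:
                self.labels = [f"CH{i}" for i in range(self.n_channels)]
        for ep in self.episodes:
            if not (0 <= ep.start < ep.end <= self.duration):
                raise ValueError(f"episode [{ep.start}, {ep.end}) outside record")
            unknown = set(ep.channels) - set(self.labels)
            if unknown:
                raise ValueError(f"episode names unknown channels {unknown}")


def _episode_signal(ep: Episode, fs: float, rng: np.random.Generator) -> np.ndarray:
    """Per-channel waveforms for one episode, shape (len(channels), n)."""
    dur = ep.end - ep.start
    p = dict(ep.params)
    kind = ep.kind
    if kind == "sync_tone":
        spec = FMSignalSpec(
            A0=p.get("amplitude", 300.0),
            f_center=p.get("freq", 3.0),
            f_dev=p.get("f_dev", 0.3),
            modulator=p.get("modulator", "sin"),
        )
        x, _ = gen_fm(spec, fs, dur, rng)
        return np.tile(x, (len(ep.channels), 1))
    if kind == "spike_wave":
        x = gen_spike_wave(p.get("rate", 1.86), fs, dur, p.get("jitter", 0.0),
                           p.get("spike_amp", 300.0), p.get("wave_amp", 150.0),
                           seed=rng)
        return np.tile(x, (len(ep.channels), 1))
    if kind == "chew_burst":
        x = gen_chew_bursts(p.get("rate", 0.71), fs, dur, p.get("jitter", 0.05),
                            p.get("amplitude", 200.0), seed=rng)
        return np.tile(x, (len(ep.channels), 1))
    if kind == "locked_pair":
        if len(ep.channels) != 2:
            raise ValueError("locked_pair episodes need exactly two channels")
        base = FMSignalSpec(
            A0=p.get("amplitude", 100.0),
            f_center=p.get("freq", 6.0),
            f_dev=p.get("f_dev", 0.5),
            modulator="randomwalk",
        )
        x, _ = gen_locked_pair(base, p.get("kappa", 20.0), fs, dur, rng)
        return x
    raise ValueError(f"unknown episode kind {kind!r}")


def gen_monitoring_record(spec: PlantedRecordSpec) -> tuple[Recording, IntervalSet]:
    """Background record with planted episodes plus the ground-truth intervals.

    Episodes on overlapping time spans sharing a channel are rejected as
    contradictory.  The truth intervals use the same half-open convention
    as the segmentation output, so interval overlap is directly scorable.
    """
    for i, a in enumerate(spec.episodes):
        for b in spec.episodes[i + 1:]:
            if a.start < b.end and b.start < a.end and set(a.channels) & set(b.channels):
                raise ValueError(
                    f"episodes [{a.start},{a.end}) and [{b.start},{b.end}) overlap "
                    "on shared channels"
                )
    rng = np.random.default_rng(spec.seed)
    samples = gen_background(spec.n_channels, spec.fs, spec.duration, rng,
                             spec.pink_rms, spec.alpha_amp, spec.rhythm_amp)
    truth: list[Interval] = []
    for ep in spec.episodes:
        sig = _episode_signal(ep, spec.fs, rng)
        i0 = int(round(ep.start * spec.fs))
        for row, lbl in zip(sig, ep.channels):
            ci = spec.labels.index(lbl)
            samples[ci, i0 : i0 + row.size] += row
        truth.append(Interval(ep.start, ep.end, ep.kind))
    rec = Recording(samples, spec.fs, list(spec.labels))
    return rec, IntervalSet(truth, "truth")


def gen_connectivity_records(
    n_channels: int = 19, fs: float = 250.0, duration: float = 60.0,
    n_locked: int = 6, kappa: float = 20.0, seed: int = 0, *,
    osc_amp: float = 40.0, pink_rms: float = 6.0, alpha_amp: float = 3.0,
) -> tuple[Recording, Recording, list[tuple[str, str]]]:
    """Paired test/rest recordings with test-only phase-locked channel pairs.

    Every channel carries its own drifting narrowband oscillation over 1/f
    background, with characteristic frequencies spread across the 3.5-9.5 Hz
    band (channels of a montage have distinct dominant rhythms; two
    independent channels therefore rarely share a ridge frequency).  In the
    *test* recording, the second member of each of ``n_locked`` disjoint
    channel pairs abandons its own rhythm and follows the first member's
    frequency track with von Mises(kappa) phase locking -- the task pulls
    the pair onto a shared rhythm.  In the *rest* recording all channels
    keep their own rhythms.  Returns (test, rest, planted pairs).
    """
    if 2 * n_locked > n_channels:
        raise ValueError("not enough channels for that many disjoint locked pairs")
    labels = (CHANNELS_1020[:n_channels] if n_channels <= len(CHANNELS_1020)
              else [f"CH{i}" for i in range(n_channels)])
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_channels)
    locked_pairs = [
        (labels[int(order[2 * i])], labels[int(order[2 * i + 1])])
        for i in range(n_locked)
    ]
    centers = np.linspace(3.5, 9.5, n_channels)[rng.permutation(n_channels)]
    f_dev = 0.12  # under half the 0.33 Hz channel spacing: distinct rhythms stay distinct

    def one_condition(plant: bool, cond_rng: np.random.Generator) -> Recording:
        samples = gen_background(n_channels, fs, duration, cond_rng,
                                 pink_rms, alpha_amp)
        done: set[str] = set()
        if plant:
            for a, b in locked_pairs:
                base = FMSignalSpec(osc_amp, float(centers[labels.index(a)]),
                                    f_dev, "randomwalk")
                x, _ = gen_locked_pair(base, kappa, fs, duration, cond_rng)
                samples[labels.index(a)] += x[0]
                samples[labels.index(b)] += x[1]
                done.update((a, b))
        for lbl in labels:
            if lbl in done:
                continue
            base = FMSignalSpec(osc_amp, float(centers[labels.index(lbl)]),
                                f_dev, "randomwalk")
            x, _ = gen_fm(base, fs, duration, cond_rng)
            samples[labels.index(lbl)] += x
        return Recording(samples, fs, list(labels))

    test = one_condition(True, np.random.default_rng(rng.integers(2**31)))
    rest = one_condition(False, np.random.default_rng(rng.integers(2**31)))
    return test, rest, locked_pairs
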