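import numpy as np
import pytest

from ridgelab import Recording, WaveletSpec, extract_ridge, morlet_cwt

FS = 256.0


@pytest.fixture(scope="session")
def default_spec():
    return WaveletSpec(fmin=0.5, fmax=22.0, df=0.05)


def tone_recording(freqs, fs=FS, duration=20.0, amplitude=1.0):
    """Multichannel recording of pure tones, one frequency per channel."""
    t = np.arange(int(duration * fs)) / fs
    samples = np.vstack([amplitude * np.sin(2 * np.pi * f * t) for f in freqs])
    labels = [f"CH{i}" for i in range(len(freqs))]
    return Recording(samples, fs, labels)


@pytest.fixture(scope="session")
def tone_ridge_5hz(default_spec):
    """Spectrogram and ridge of a 20 s, 5 Hz unit tone (shared, read-only)."""
    t = np.arange(int(20 * FS)) / FS
    sg = morlet_cwt(np.sin(2 * np.pi * 5.0 * t), FS, default_spec, channel="A")
    return sg, extract_ridge(sg)
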