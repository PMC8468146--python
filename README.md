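# ridgelab

Wavelet-ridge analysis of multichannel EEG: screening long-term epilepsy
monitoring recordings for seizure-suspicious fragments, telling epileptic
discharges apart from chewing artifacts, and mapping phase-connected
channel pairs during cognitive testing.

## The problem

Clinical EEG review does not scale: days of 19-channel monitoring must be
read by an expert to find minutes of seizure activity, and resting or
task EEG must be compared across conditions to assess cognitive recovery
after brain injury.  Both problems reduce to tracking *instantaneous*
frequency, amplitude and phase of a non-stationary oscillation — which is
exactly what the ridge of a continuous wavelet spectrogram provides.

## The core quantity

For a signal `S(t)` the complex Morlet wavelet transform is

    W(a, b) = (1 / (a sqrt(pi f_b))) ∫ S(t) exp(-((t-b)/a)^2 / f_b)
                                           exp(-2 pi i f_c (t-b)/a) dt

with `f_b = f_c = 1` and the scale mapped to analysis frequency by
`f = f_c / a`.  The **ridge** is the per-time absolute maximum of `|W|`
over frequency.  By the stationary-phase approximation, for oscillations
whose amplitude varies slowly relative to their phase, the ridge carries
the signal itself:

* `fr(t) = argmax_f |W(f, t)|` — instantaneous frequency,
* `|W(fr, t)|` — instantaneous envelope amplitude (PSD after squaring),
* `Φ(t) = arg W(fr, t)` or the frequency-modulation form `Φ = 2π fr(t) t`
  — instantaneous phase,

valid where `|fr'| / (2 fr²) ≪ 1`.  Three analyses are built on it:

1. **Segmentation** (`ridgelab.segmentation`): channel pairs whose ridge
   frequencies stay within ε = 0.5 Hz are "synchronized"; ridge-PSD
   segments above an adaptively chosen threshold mark high-power activity;
   the *intersection* of the two interval families is the set of
   seizure-suspicious fragments handed to the reviewer.
2. **Artifact discrimination** (`ridgelab.artifacts`): the Fourier
   spectrum of a fixed-frequency slice of the spectrogram (taken above the
   ridge, default 4 Hz) peaks at the repetition rate of a rhythmic event;
   discharges repeat faster and more regularly than chewing, so peak
   frequency and full width at half maximum separate them.
3. **Phase connectivity** (`ridgelab.connectivity`): per channel pair, the
   ridge-phase difference is histogrammed; the tallest-bin height ρ is
   compared between a cognitive-test recording (A) and rest (B); pairs
   beyond the sharp knee of the sorted contrast `D = A − B` are reported
   as phase-connected, with an explicit "not identifiable" outcome when no
   knee exists.

Because clinical recordings cannot be redistributed, `ridgelab.synth`
generates surrogate EEG with known ground truth (drifting narrowband
oscillations, spike–wave trains, chewing-like bursts, 1/f background,
planted phase-locked pairs) for every analysis above.

## Worked example

Discriminate a spike–wave discharge surrogate from a chewing surrogate:

```python
from ridgelab import WaveletSpec, morlet_cwt
from ridgelab.artifacts import spectrogram_slice, slice_fourier, discriminate
from ridgelab.synth import gen_spike_wave, gen_chew_bursts

fs, band = 256.0, WaveletSpec(fmin=0.5, fmax=22.0)

def features(x):
    sg = morlet_cwt(x, fs, band)
    series, _, fcur = spectrogram_slice(sg, 4.0)   # slice above the ridge
    return slice_fourier(series, fs, fcur)

es   = features(gen_spike_wave(1.86, fs, 60.0))    # discharge at 1.86 Hz
chew = features(gen_chew_bursts(0.71, fs, 60.0))   # chewing at ~0.71 Hz

print(f"discharge: peak {es.peak_freq:.3f} Hz, FWHM {es.fwhm:.3f} Hz")
print(f"chewing:   peak {chew.peak_freq:.3f} Hz, FWHM {chew.fwhm:.3f} Hz")
print(discriminate(es, chew))
```

prints

```
discharge: peak 1.867 Hz, FWHM 0.031 Hz
chewing:   peak 0.667 Hz, FWHM 0.083 Hz
{'verdict': 'first-ES-like', 'peak_ratio': 2.80, 'fwhm_ratio': 0.38}
```

The discharge slice pulses ~2.6–2.8× faster than chewing and its spectral
line is ~2.6× narrower — the two features the discriminator uses.  The
same machinery is available from the shell:

```bash
ridgelab simulate --preset monitoring --seed 42 -o rec.edf --truth truth.csv
ridgelab segment rec.edf -o intervals.csv --report report.json
ridgelab connect --test test.edf --rest rest.edf -o network.json
```

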