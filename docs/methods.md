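# Methods

## Wavelet transform and ridge

The analysis wavelet is the complex Morlet
`psi(t) = (pi f_b)^(-1/2) exp(-t^2/f_b) exp(2 pi i f_c t)` with
`f_b = f_c = 1`.  The transform is evaluated in the Fourier domain with the
transfer function `H_a(f) = exp(-pi^2 f_b (a f - f_c)^2)`, which is the
exact continuous-time frequency response of the kernel under the
normalization `1/(a sqrt(pi f_b))`.  Two consequences of this
normalization drive the design:

* the ridge of a pure tone sits exactly at the tone frequency (an
  L2-normalized transform carries a `sqrt(a)` factor that biases the
  argmax low by about one grid step at 2 Hz);
* the ridge modulus of a real tone equals its envelope amplitude (a
  factor 2 restores the energy that the analytic-side transfer function
  removes from negative frequencies), so ridge PSD
  (`modulus^2 / df`, in uV^2/Hz) is on a physically interpretable scale.

The frequency grid is linear, default step `df = 0.05` Hz — an order finer
than the 0.5 Hz synchronization tolerance that consumes ridge
frequencies.  Scales follow `a = f_c / f`.  Signals are zero-padded by
`4 / fmin` seconds so the widest kernel's tails never wrap.

**Ridge extraction** takes the per-time argmax of the modulus, breaking
ties toward the lower frequency (deterministic and reproducible).  A
streaming variant (`ridge_from_signal`) processes the frequency grid in
blocks and keeps only the running maximum, its frequency and its complex
coefficient, making multi-hour records tractable in O(block x n) memory;
it is bit-identical to the full-spectrogram path (tested).

**Edge handling.**  Samples within `2/f` seconds of either record edge at
their own ridge frequency are inside the cone of influence and flagged
invalid.  The stationary-phase validity condition is implemented as
`|fr'| / (2 fr^2) < 0.1`, quantifying "much less than one" as one order of
magnitude; on a grid-quantized ridge the derivative spikes at isolated
bin transitions, so those single samples drop out — harmless in every
consumer, which either masks or counts valid samples.

**Phase.**  Two estimators are provided: the direct four-quadrant angle
of the coefficient at the ridge, and the frequency-modulation form
`Phi = 2 pi fr(t) t`.  The FM form is the default for connectivity: it
turns phase comparison into ridge-frequency-track comparison, which
yields a much sharper lock histogram (the direct angle inherits coefficient
noise).  Its flip side is documented under Limitations.

## Preprocessing

Outliers are removed per channel with the X84 rule (|x - median| >
5.2 MAD), replaced by linear interpolation from the nearest inliers so
the time axis stays intact for the transform; a channel with MAD = 0 and
deviating samples passes through with a warning.  Power-line interference
is removed with one zero-phase IIR band-stop (Q = 30) per 50 Hz harmonic
below Nyquist; task recordings additionally get a fourth-order zero-phase
Butterworth bandpass (2-10 Hz).  All filters run forward-backward so
ridge phases inherit no filter phase distortion.

Pipelines resample internally (polyphase, anti-aliased) to the largest
integer-divisor rate of at least 2.5 x fmax — e.g. 256 Hz records are
analyzed at 64 Hz for a 22 Hz band — which keeps long-record transforms
tractable without touching the analysis band.  Ridge series are reported
on the resampled time base.

## Segmentation

Pairwise synchronization is `|fr_i(k) - fr_j(k)| <= 0.5 Hz` (boundary
inclusive) on samples valid in both ridges.  Runs of synchronized samples
become fragments; fragments separated by less than 10 s merge; fragments
shorter than 10 s are then discarded.  Merging precedes the duration
filter, so two sub-threshold runs close together survive as one fragment.
Record-level synchronized intervals are spans where at least `min_pairs`
pairs (default 1, i.e. "at least two channels") are simultaneously inside
a fragment.

The PSD screen scans 200 candidate thresholds from 0 to the 99.9th PSD
percentile, counts supra-threshold ridge segments per candidate, smooths
the count curve (moving average, window 5) and takes its discrete second
difference.  The knee — where the count collapse out of the noise floor
ends — is anchored at the last region where |d2| reaches 10% of its
maximum; the chosen threshold sits at the quiet onset just beyond, plus
half a smoothing window (the moving average smears the knee by exactly
that margin).  A featureless record has no knee: the scan midpoint is
returned with an explicit warning rather than silently.  Thresholds are
chosen independently per channel (power scales differ across electrodes)
and the resulting intervals are unioned across channels; supra-threshold
runs shorter than 1 s are dropped as noise excursions — an isolated
sample above a 99.9th-percentile-range threshold is not a discharge-scale
event.

The pipeline output is the intersection of the synchronization and PSD
interval families, coalesced into plain "hit" spans; the report carries
per-stage counts, retained duration, and the reduction factor (record
duration over retained duration).

## Artifact discrimination

The slice series `|W(f_cur, t)|` (default `f_cur` = 4 Hz, warned if not
above the window's median ridge frequency) is analyzed with a
mean-removed, Hann-tapered periodogram.  The main peak is the power
maximum above 0.2 Hz (excluding the DC shoulder); FWHM is measured by
linear interpolation at half peak power; `n_peaks` counts peaks reaching
25% of the maximum.  At 60 s windows the spectral bin is 1/60 Hz, which
bounds rate-recovery accuracy.

Note the wavelet's own time resolution at the slice frequency (Gaussian,
sigma = a sqrt(f_b/2) ~ 0.18 s at 4 Hz) low-passes the slice series:
harmonics of repetition rates above ~2 Hz are suppressed by orders of
magnitude and are not observable in slice spectra, whatever the waveform.

## Synthetic data

The generators define the conditions every quantitative test runs under;
all are deterministic given a seed.

* **FM oscillations** `x = A0 sin(2 pi ∫ f dt)`, f = f_center + f_dev *
  xi(t), with constant, linear (chirp), sinusoidal or smoothed-random-walk
  modulators; ground-truth instantaneous frequency is returned alongside.
* **Spike-wave trains**: a 70 ms biphasic spike (broadband, reaching well
  above 4 Hz) followed by a 250 ms half-sine wave, repeating at the given
  rate.  Consecutive complexes alternate in amplitude by +-10% (the
  waxing-waning prominence of real runs); this places a second, subharmonic
  peak at half the repetition rate in the slice spectrum, standing in for
  the multi-peak structure of clinical spike-wave slice spectra that
  harmonic peaks cannot provide under the wavelet's time resolution (see
  above).
* **Chewing bursts**: Gaussian-enveloped 5 Hz bursts (sd 120 ms) at
  ~0.71 Hz.  Period jitter is *cumulative* (each period drawn
  N(1/rate, sigma)), so the rhythm genuinely loses long-range stability
  and its spectral line broadens, rather than merely losing power to a
  flat floor as independently displaced events would.  The default jitter
  of 0.25 s (~18% of the period) encodes that chewing is a voluntary,
  unstable rhythm; discharges default to zero jitter.  This is what makes
  the chewing FWHM the larger of the two.
* **Background**: 1/f noise plus a weak 10 Hz alpha component; the
  monitoring preset adds a per-channel dominant rhythm at a
  channel-specific frequency (4.5-18 Hz, slight drift).  Pure 1/f
  background pins every channel's ridge at the bottom of the band, which
  would make all pairs trivially "synchronized"; distinct dominant
  rhythms above the delta band reflect an awake resting background and
  leave the delta range to the pathological events planted on top.
* **Locked pairs**: two channels share one frequency track; the second
  channel's phase offset follows a slowly varying process whose anchors
  (1 per second, interpolated) are drawn von Mises(0, kappa).  kappa = 20
  keeps the offset within ~0.2 rad (locked); kappa = 0 lets it wander the
  circle (independent).  In the connectivity generator, channels carry
  distinct characteristic frequencies spread over 3.5-9.5 Hz with
  +-0.12 Hz drift — under half the spacing — so independent channels'
  tracks do not collide by chance (see Limitations).

What the surrogates do **not** model: realistic seizure morphology and
evolution, volume conduction and shared reference effects, ocular or
electrode artifacts, inter-subject variability.  Passing tests therefore
demonstrate that the algorithms recover what they are defined to measure
under controlled conditions, not clinical sensitivity or specificity.

## Connectivity detection

Phase-difference histograms use 100 uniform bins over (-pi, pi], with one
bin centred on zero so the |dPhi| < 0.01 pi lock criterion coincides with
the central bin; portions are normalized by the total number of reference
points, so histogram mass equals the valid fraction.  The contrast
`D = A - B` (A, B = tallest-bin heights in test and rest) is sorted
ascending; the knee of its derivative separates connected pairs.

A derivative value qualifies as the knee only if it exceeds all of:
5 x the median positive derivative (it stands out against the curve's
typical step), 25% of the maximum derivative (baseline wiggles on a flat
curve cannot qualify), and the interquartile spread of D (consecutive
order statistics of pure noise sit far closer together than the bulk
spread, so a knee-free noise curve offers no qualifying gap); the
contrast at the knee must be positive (a pair more locked during the task
than at rest must gain), and the mean derivative over the tail must stay
above the median-based level.  When no index qualifies the result is an
explicit "not identifiable" flag with an empty network — the honest
outcome for a contrast curve that never steps up.

## Problem sizes

Quantitative checks run at desk scale, as the package's own choice of
study size: 60 s records at 256 Hz for ridge and slice statistics; a
30-minute 6-channel record with three planted episodes for the
segmentation pipeline; 19 channels / 171 pairs / 6 planted locked pairs,
20 seeds, for connectivity recovery; 10 seeds of 2000 s planted-burst
ridges for the adaptive threshold.

## Known limitations

* The FM phase `2 pi fr t` depends only on the ridge-frequency track, so
  *any* pair of channels whose tracks coincide — a shared rhythm, not
  just a locked one — reads as phase-locked.  The connectivity contrast
  D subtracts the rest condition, which removes persistent shared
  rhythms, but task-evoked common rhythms would still inflate D.  This
  is inherent to the method, and it is why the synthetic background gives
  channels distinct characteristic frequencies.
* The adaptive threshold assumes the PSD distribution is noise-dominated
  with a minority of high-power events; on a record that is mostly
  seizure the knee would sit inside the events.
* Slice-spectrum harmonics above ~2 Hz are unobservable (wavelet time
  resolution); repetition rates are recoverable, harmonic structure is
  not.
* EDF support covers plain continuous EDF with equal per-channel rates;
  EDF+ annotations and discontinuous records are out of scope.
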