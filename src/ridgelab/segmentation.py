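"""Segmentation of long multichannel EEG into seizure-suspicious fragments.

Two independent screens are intersected: (i) intervals where the ridge
frequencies of at least one channel pair stay within epsilon of each other
(interchannel synchronization), and (ii) intervals where the ridge spectral
power density exceeds an adaptively chosen threshold.  Generalized
discharges produce both signatures at once, so their intersection is a
drastically smaller set of fragments for expert review.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .io import Interval, IntervalSet, Recording
from .preprocess import notch_filter
from .wavelet import Ridge, WaveletSpec, ridge_from_signal, validity_mask

__all__ = [
    "SyncSeries",
    "ThresholdScan",
    "SegmentationReport",
    "pairwise_sync",
    "sync_fragments",
    "record_sync_intervals",
    "threshold_segments",
    "adaptive_threshold",
    "intersect_interval_sets",
    "segment_pipeline",
    "LONGITUDINAL_PAIRS_1020",
]

#: The 19 longitudinal neighbor pairs of the 10-20 montage (the pair preset
#: used for pairwise raster displays of clinical recordings).
LONGITUDINAL_PAIRS_1020: list[tuple[str, str]] = [
    ("Fp1", "F7"), ("F7", "T3"), ("T3", "T5"), ("T5", "O1"),
    ("Fp1", "F3"), ("F3", "C3"), ("C3", "P3"), ("P3", "O1"),
    ("Fz", "Cz"), ("Cz", "Pz"), ("Fz", "Pz"),
    ("Fp2", "F4"), ("F4", "C4"), ("C4", "P4"), ("P4", "O2"),
    ("Fp2", "F8"), ("F8", "T4"), ("T4", "T6"), ("T6", "O2"),
]


@dataclass
class SyncSeries:
    """Per-sample synchronization flag for one channel pair."""

    pair: tuple[str, str]
    sync: np.ndarray          # boolean per ridge sample
    times: np.ndarray         # seconds, common time base
    epsilon: float            # Hz

    def __post_init__(self) -> None:
        if self.sync.size != self.times.size:
            raise ValueError("sync/times length mismatch")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")


@dataclass
class ThresholdScan:
    """Segment counts versus candidate PSD thresholds, and the chosen knee."""

    thresholds: np.ndarray    # uV^2/Hz, strictly increasing
    seg_counts: np.ndarray    # raw segment count per threshold
    smoothed: np.ndarray      # moving-average of seg_counts
    d2: np.ndarray            # discrete second difference of the smoothed counts
    chosen: float             # uV^2/Hz
    knee_found: bool = True


@dataclass
class SegmentationReport:
    """Per-stage bookkeeping for one pipeline run."""

    record_duration: float
    n_sync_fragments: int
    sync_duration: float
    n_psd_segments: int
    psd_duration: float
    n_intersections: int
    retained_duration: float
    thresholds: dict[str, float]

    @property
    def reduction_factor(self) -> float:
        """Record duration over retained duration (inf when nothing retained)."""
        if self.retained_duration == 0:
            return float("inf")
        return self.record_duration / self.retained_duration

    def as_dict(self) -> dict:
        d = self.__dict__.copy()
        d["reduction_factor"] = self.reduction_factor
        return d


def pairwise_sync(ridge_i: Ridge, ridge_j: Ridge, epsilon: float = 0.5) -> SyncSeries:
    """Synchronization flag: |fr_i(k) - fr_j(k)| <= epsilon, both samples valid.

    The comparison boundary is inclusive.  epsilon defaults to 0.5 Hz, the
    smallest separation at which two nearby spectral peaks remain
    distinguishable on the analysis grid.
    """
    if ridge_i.times.size != ridge_j.times.size or not np.allclose(
        ridge_i.times, ridge_j.times
    ):
        raise ValueError("ridges are not on a common time base")
    sync = (np.abs(ridge_i.fr - ridge_j.fr) <= epsilon) & ridge_i.valid & ridge_j.valid
    return SyncSeries((ridge_i.channel, ridge_j.channel), sync, ridge_i.times, epsilon)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as half-open index pairs."""
    if mask.size == 0:
        return []
    m = mask.astype(np.int8)
    edges = np.flatnonzero(np.diff(m))
    starts = list(edges[m[edges] == 0] + 1)
    ends = list(edges[m[edges] == 1] + 1)
    if m[0]:
        starts.insert(0, 0)
    if m[-1]:
        ends.append(mask.size)
    return list(zip(starts, ends))


def _mask_to_intervals(mask: np.ndarray, times: np.ndarray, dt: float,
                       label: str) -> list[Interval]:
    return [
        Interval(float(times[i0]), float(times[i1 - 1] + dt), label)
        for i0, i1 in _runs(mask)
    ]


def sync_fragments(s: SyncSeries, merge_gap: float = 10.0,
                   min_dur: float = 10.0) -> IntervalSet:
    """Assemble synchronized samples into fragments.

    Maximal runs of sync=1 become intervals; fragments separated by less
    than ``merge_gap`` seconds are combined into one; fragments shorter than
    ``min_dur`` seconds are then discarded.  Merging runs before the
    duration filter, so short runs can combine into a keepable fragment.
    """
    dt = float(np.median(np.diff(s.times))) if s.times.size > 1 else 0.0
    ivs = _mask_to_intervals(s.sync, s.times, dt, "sync")
    merged: list[Interval] = []
    for iv in ivs:
        if merged and iv.start - merged[-1].end < merge_gap:
            merged[-1] = Interval(merged[-1].start, iv.end, "sync")
        else:
            merged.append(iv)
    kept = [iv for iv in merged if iv.duration >= min_dur]
    return IntervalSet(kept, f"{s.pair[0]}-{s.pair[1]}")


def record_sync_intervals(all_pairs: list[SyncSeries], min_pairs: int = 1,
                          merge_gap: float = 10.0, min_dur: float = 10.0) -> IntervalSet:
    """Record-level synchronized intervals from per-pair fragments.

    Returns time spans during which at least ``min_pairs`` pairs are
    simultaneously inside one of their own fragments; with the default of
    one pair this reads "at least two channels synchronized".  Interval
    labels list the contributing pairs.
    """
    if min_pairs < 1:
        raise ValueError("min_pairs must be >= 1")
    if not all_pairs:
        return IntervalSet([])
    frag_sets = [sync_fragments(s, merge_gap, min_dur) for s in all_pairs]
    edges = sorted({e for fs_ in frag_sets for iv in fs_ for e in (iv.start, iv.end)})
    out: list[Interval] = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        mid = 0.5 * (lo + hi)
        owners = [
            fs_.channel_or_pair
            for fs_ in frag_sets
            if any(iv.start <= mid < iv.end for iv in fs_)
        ]
        if len(owners) >= min_pairs:
            out.append(Interval(lo, hi, "+".join(sorted(filter(None, owners)))))
    # adjacent cells with identical contributor sets coalesce
    merged: list[Interval] = []
    for iv in out:
        if merged and merged[-1].end == iv.start and merged[-1].label == iv.label:
            merged[-1] = Interval(merged[-1].start, iv.end, iv.label)
        else:
            merged.append(iv)
    return IntervalSet(merged, "sync")


def threshold_segments(ridge: Ridge, tr: float) -> IntervalSet:
    """Maximal runs of ridge samples with PSD >= tr, as intervals."""
    if tr <= 0:
        raise ValueError("threshold must be positive")
    dt = 1.0 / ridge.fs
    ivs = _mask_to_intervals(ridge.psd >= tr, ridge.times, dt, "psd")
    return IntervalSet(ivs, ridge.channel)


def adaptive_threshold(ridge: Ridge, scan_points: int = 200,
                       smooth_window: int = 5,
                       negligible_frac: float = 0.10) -> ThresholdScan:
    """Choose a PSD threshold from the knee of the segment-count curve.

    The number of supra-threshold ridge segments is scanned over a grid of
    candidate thresholds up to the 99.9th PSD percentile.  As the threshold
    climbs out of the noise floor the count collapses; the second difference
    of the (smoothed) count curve peaks at that collapse and is negligible
    beyond it.  ``chosen`` is the threshold at the most prominent local
    maximum of the second difference after which its magnitude stays below
    ``negligible_frac`` of the global maximum.  With no such maximum (e.g. a
    featureless record) the scan midpoint is returned with a warning.
    """
    if scan_points < 3:
        raise ValueError("need at least 3 scan points")
    psd = ridge.psd
    hi = float(np.percentile(psd, 99.9))
    if hi <= 0:
        raise ValueError("ridge PSD is identically zero")
    thresholds = np.linspace(hi / scan_points, hi, scan_points)
    counts = np.array([len(_runs(psd >= tr)) for tr in thresholds], dtype=float)
    kernel = np.ones(smooth_window) / smooth_window
    pad = smooth_window // 2
    smoothed = np.convolve(np.pad(counts, pad, mode="edge"), kernel, mode="valid")
    d2 = np.zeros_like(smoothed)
    d2[1:-1] = np.diff(smoothed, 2)
    chosen = None
    if np.abs(d2).max() > 0:
        ceiling = negligible_frac * np.abs(d2).max()
        loud = np.flatnonzero(np.abs(d2) >= ceiling)
        # knee anchor: the most prominent convex turn of the count curve
        # must live in the last non-negligible |d2| region...
        anchor = int(loud[-1])
        run_start = anchor
        while run_start > 0 and np.abs(d2[run_start - 1]) >= ceiling:
            run_start -= 1
        has_peak = d2[run_start : anchor + 1].max() > 0
        # ...and the threshold is taken where |d2| first stays negligible
        # beyond that knee: the count curve has finished collapsing there.
        # The moving average smears the knee by half a window, so step that
        # margin past the quiet onset to reach the true end of the collapse.
        quiet = anchor + 1 + smooth_window // 2
        if has_peak and quiet < thresholds.size:
            chosen = float(thresholds[quiet])
    if chosen is None:
        warnings.warn(
            "no knee in the segment-count curve; falling back to the scan midpoint",
            RuntimeWarning,
        )
        return ThresholdScan(thresholds, counts, smoothed, d2,
                             float(thresholds[scan_points // 2]), knee_found=False)
    return ThresholdScan(thresholds, counts, smoothed, d2, chosen)


def intersect_interval_sets(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    """Pairwise intersections of overlapping intervals from two sets.

    Provenance labels carry both parents as "labelA&labelB".
    """
    out: list[Interval] = []
    for ia in a:
        for ib in b:
            lo, hi = max(ia.start, ib.start), min(ia.end, ib.end)
            if lo < hi:
                label = "&".join(x for x in (ia.label, ib.label) if x) or "intersection"
                out.append(Interval(lo, hi, label))
    return IntervalSet(out).normalize()


def segment_pipeline(rec: Recording, *,
                     spec: WaveletSpec | None = None,
                     epsilon: float = 0.5,
                     merge_gap: float = 10.0,
                     min_dur: float = 10.0,
                     min_pairs: int = 1,
                     pairs: list[tuple[str, str]] | None = None,
                     threshold: float | None = None,
                     psd_min_dur: float = 1.0,
                     notch_base: float | None = 50.0,
                     target_fs: float | None = None) -> tuple[IntervalSet, SegmentationReport]:
    """Full segmentation chain for one recording.

    Stages: notch filtering, Morlet CWT, ridge extraction, pairwise
    synchronization intervals, adaptive per-channel PSD thresholding (union
    over channels), and intersection of the two interval families.  Returns
    the intersected intervals plus a per-stage report with the reduction
    factor (record duration over retained duration).

    ``pairs`` selects the channel pairs to test (default: all unordered
    pairs; ``LONGITUDINAL_PAIRS_1020`` is the montage-neighbor preset).
    ``threshold`` overrides the adaptive PSD threshold for every channel;
    supra-threshold runs shorter than ``psd_min_dur`` seconds are dropped
    as noise blips before intersection (a discharge-scale duration floor).
    ``target_fs`` resamples before the CWT (default: a divisor of fs giving
    at least 2.5 x fmax).
    """
    from .preprocess import butterworth_bandpass  # noqa: F401  (re-export convenience)
    from scipy.signal import resample_poly

    if rec.n_channels < 2:
        raise ValueError("segmentation needs at least 2 channels")
    spec = spec or WaveletSpec(fmin=0.5, fmax=22.0)
    if notch_base is not None and notch_base < rec.fs / 2:
        rec = notch_filter(rec, notch_base,
                           n_harmonics=max(1, int(rec.fs / 2 / notch_base)))

    fs = rec.fs
    samples = rec.samples
    if target_fs is None:
        k = max(1, int(fs // (2.5 * spec.fmax)))
        target_fs = fs / k
    if target_fs < fs:
        up, down = 1, int(round(fs / target_fs))
        samples = resample_poly(samples, up, down, axis=-1)
        fs = fs / down

    ridges = {
        lbl: validity_mask(ridge_from_signal(ch, fs, spec, channel=lbl,
                                             t0=rec.start_time))
        for lbl, ch in zip(rec.labels, samples)
    }

    if pairs is None:
        labels = rec.labels
        pairs = [(labels[i], labels[j]) for i in range(len(labels))
                 for j in range(i + 1, len(labels))]
    sync_series = [
        pairwise_sync(ridges[a], ridges[b], epsilon)
        for a, b in pairs if a in ridges and b in ridges
    ]
    sync_ivs = record_sync_intervals(sync_series, min_pairs, merge_gap, min_dur)

    psd_ivs_all: list[Interval] = []
    chosen: dict[str, float] = {}
    for lbl, ridge in ridges.items():
        tr = threshold if threshold is not None else adaptive_threshold(ridge).chosen
        chosen[lbl] = tr
        psd_ivs_all.extend(iv for iv in threshold_segments(ridge, tr)
                           if iv.duration >= psd_min_dur)
    psd_ivs = IntervalSet([Interval(iv.start, iv.end, "psd") for iv in psd_ivs_all]).normalize()

    raw = intersect_interval_sets(sync_ivs, psd_ivs)
    # pipeline verdicts are plain "hit" spans: adjacent pieces that differ
    # only in contributing pairs coalesce into one reviewable fragment
    hits = IntervalSet([Interval(iv.start, iv.end, "hit") for iv in raw]).normalize()
    report = SegmentationReport(
        record_duration=rec.duration,
        n_sync_fragments=len(sync_ivs),
        sync_duration=sync_ivs.total_duration,
        n_psd_segments=len(psd_ivs),
        psd_duration=psd_ivs.total_duration,
        n_intersections=len(hits),
        retained_duration=hits.total_duration,
        thresholds=chosen,
    )
    return hits, report
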