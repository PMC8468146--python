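"""Ridge-phase interchannel connectivity for cognitive-test recordings.

For every channel pair the phase difference at the ridge points is
histogrammed; the height of the tallest bin (the lock portion rho) is
compared between a cognitive-test recording (A) and a task-free rest
recording (B).  Pairs whose contrast D = A - B lies beyond the sharp knee
of the sorted-D derivative curve are reported as phase-connected; when the
derivative never increases sharply, the recording is flagged as not
identifiable rather than forcing a network out of noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .io import Recording
from .preprocess import butterworth_bandpass, huber_x84_clean, notch_filter
from .wavelet import Ridge, WaveletSpec, ridge_from_signal, ridge_phase_direct, \
    ridge_phase_fm, validity_mask, wrap_phase

__all__ = [
    "PhaseHistogram",
    "ContrastCurve",
    "phase_difference",
    "phase_histogram",
    "contrast_curve",
    "detect_connected_pairs",
    "connectivity_pipeline",
    "export_network",
]

#: default lock tolerance |dPhi| < 0.01*pi radians
LOCK_TOL = 0.01 * np.pi


@dataclass
class PhaseHistogram:
    """Normalized histogram of the interchannel ridge-phase difference.

    ``portions`` are bin counts divided by N, the *total* number of ridge
    reference points in the recording (not just the valid ones), so the
    histogram mass equals the valid fraction and rho_max is comparable
    across pairs with different dropout.
    """

    pair: tuple[str, str]
    bin_edges: np.ndarray     # radians, uniform over (-pi, pi]
    portions: np.ndarray
    n_locked: int             # samples with |dPhi| < lock_tol
    N: int                    # total reference points
    rho_max: float = field(init=False)

    def __post_init__(self) -> None:
        self.rho_max = float(self.portions.max()) if self.portions.size else 0.0

    @property
    def lock_fraction(self) -> float:
        """Scalar lock portion n/N."""
        return self.n_locked / self.N


@dataclass
class ContrastCurve:
    """Sorted test-minus-rest contrast D per channel pair, with detection."""

    pairs: list[tuple[str, str]]   # in ascending-D order
    D: np.ndarray
    deriv: np.ndarray              # first differences (deriv[0] = 0)
    knee_index: int | None = None
    connected: list[tuple[str, str]] = field(default_factory=list)
    identifiable: bool = True


def phase_difference(ridge_x: Ridge, ridge_y: Ridge,
                     method: str = "fm") -> tuple[np.ndarray, np.ndarray, int]:
    """Wrapped phase difference at the common valid ridge points.

    ``method`` selects the frequency-modulation phase 2*pi*fr*t ("fm", the
    default: it yields the sharper lock histogram) or the direct
    four-quadrant coefficient angle ("direct").  Returns (times, dphi,
    n_total) where n_total is the length of the common time base before
    validity masking.
    """
    if ridge_x.times.size != ridge_y.times.size or not np.allclose(
        ridge_x.times, ridge_y.times
    ):
        raise ValueError("ridges are not on a common time base")
    if method == "fm":
        rx, ry = ridge_phase_fm(ridge_x), ridge_phase_fm(ridge_y)
    elif method == "direct":
        rx, ry = ridge_phase_direct(ridge_x), ridge_phase_direct(ridge_y)
    else:
        raise ValueError(f"unknown phase method {method!r}")
    ok = rx.valid & ry.valid
    if not ok.any():
        raise ValueError("no common valid ridge samples")
    dphi = wrap_phase(rx.phase[ok] - ry.phase[ok])
    return ridge_x.times[ok], dphi, ridge_x.times.size


def phase_histogram(dphi: np.ndarray, n_bins: int = 100,
                    lock_tol: float = LOCK_TOL, n_total: int | None = None,
                    pair: tuple[str, str] = ("x", "y")) -> PhaseHistogram:
    """Histogram the phase differences into uniform bins over (-pi, pi].

    With the default 100 bins (width 0.02*pi) the central bin matches the
    |dPhi| < 0.01*pi lock criterion.
    """
    dphi = np.asarray(dphi, dtype=float)
    N = int(n_total) if n_total is not None else dphi.size
    if N == 0 or dphi.size == 0:
        raise ValueError("no phase samples to histogram")
    # bins centred so that one bin straddles zero symmetrically
    width = 2 * np.pi / n_bins
    edges = -np.pi - width / 2 + width * np.arange(n_bins + 2)
    counts, _ = np.histogram(dphi, bins=edges)
    # first and last bins are the two halves of the same wrapped bin
    counts[-1] += counts[0]
    counts = counts[1:]
    edges = edges[1:]
    n_locked = int(np.count_nonzero(np.abs(dphi) < lock_tol))
    return PhaseHistogram(pair, edges, counts / N, n_locked, N)


def contrast_curve(test_hists: dict[tuple[str, str], PhaseHistogram],
                   rest_hists: dict[tuple[str, str], PhaseHistogram]) -> ContrastCurve:
    """Per-pair contrast D = A - B, sorted ascending.

    A and B are rho_max in the test and rest condition.  Pair identity
    follows the sort; the derivative is by first differences.
    """
    if set(test_hists) != set(rest_hists):
        raise ValueError("test and rest conditions cover different pair sets")
    pairs = list(test_hists)
    D = np.array([test_hists[p].rho_max - rest_hists[p].rho_max for p in pairs])
    order = np.argsort(D, kind="stable")
    pairs = [pairs[i] for i in order]
    D = D[order]
    deriv = np.zeros_like(D)
    if D.size > 1:
        deriv[1:] = np.diff(D)
    return ContrastCurve(pairs, D, deriv)


def detect_connected_pairs(curve: ContrastCurve, knee_factor: float = 5.0,
                           sharp_frac: float = 0.25) -> ContrastCurve:
    """Find the sharp increase of the sorted-D derivative and split the curve.

    A derivative value counts as "sharp" when it exceeds all of:
    ``knee_factor`` times the median positive derivative (it stands out
    against the typical step of the curve); ``sharp_frac`` of the largest
    derivative (it is of the same order as the sharpest step, so baseline
    wiggles on a nearly flat curve cannot qualify); and the interquartile
    spread of D itself (consecutive order statistics of pure noise sit far
    closer together than the bulk spread, so a knee-free noise curve has
    no qualifying gap).  The knee is
    the first sharp index with positive contrast -- a pair more locked in
    the test than at rest must gain, not lose -- whose tail keeps the mean
    derivative above the median-based level.  Pairs at and beyond the knee
    are connected.  Without such an index the curve is declared not
    identifiable and no pairs are returned.
    """
    if len(curve.pairs) < 3:
        raise ValueError("need at least 3 pairs")
    deriv, D = curve.deriv, curve.D
    pos = deriv[deriv > 0]
    flagged = replace(curve, knee_index=None, connected=[], identifiable=False)
    if pos.size == 0:
        return flagged
    level = knee_factor * float(np.median(pos))
    q25, q75 = np.percentile(D, [25, 75])
    thresh = max(level, sharp_frac * float(deriv.max()), float(q75 - q25))
    for i in range(1, deriv.size):
        if deriv[i] > thresh and D[i] > 0 and deriv[i:].mean() > level:
            return replace(curve, knee_index=i,
                           connected=curve.pairs[i:], identifiable=True)
    return flagged


def connectivity_pipeline(test_rec: Recording, rest_rec: Recording, *,
                          spec: WaveletSpec | None = None,
                          method: str = "fm",
                          n_bins: int = 100,
                          lock_tol: float = LOCK_TOL,
                          knee_factor: float = 5.0,
                          band: tuple[float, float] = (2.0, 10.0),
                          notch_base: float | None = 50.0,
                          target_fs: float | None = None) -> ContrastCurve:
    """Full connectivity chain: preprocessing through knee detection.

    Stages: X84 outlier cleaning, notch, zero-phase Butterworth bandpass
    (default 2-10 Hz), Morlet CWT on a 1-25 Hz grid, ridge extraction, ridge
    phases, per-pair phase-difference histograms in both conditions, sorted
    contrast curve and knee detection over all unordered channel pairs.
    """
    from scipy.signal import resample_poly

    if test_rec.labels != rest_rec.labels:
        raise ValueError("test and rest recordings must share a montage")
    spec = spec or WaveletSpec(fmin=1.0, fmax=25.0)

    def ridges_of(rec: Recording) -> dict[str, Ridge]:
        rec = huber_x84_clean(rec)
        if notch_base is not None and notch_base < rec.fs / 2:
            rec = notch_filter(rec, notch_base,
                               n_harmonics=max(1, int(rec.fs / 2 / notch_base)))
        rec = butterworth_bandpass(rec, band[0], band[1])
        fs, samples = rec.fs, rec.samples
        tfs = target_fs
        if tfs is None:
            k = max(1, int(fs // (2.5 * spec.fmax)))
            tfs = fs / k
        if tfs < fs:
            down = int(round(fs / tfs))
            samples = resample_poly(samples, 1, down, axis=-1)
            fs = fs / down
        return {
            lbl: validity_mask(ridge_from_signal(ch, fs, spec, channel=lbl))
            for lbl, ch in zip(rec.labels, samples)
        }

    test_ridges = ridges_of(test_rec)
    rest_ridges = ridges_of(rest_rec)
    labels = test_rec.labels
    pairs = [(labels[i], labels[j]) for i in range(len(labels))
             for j in range(i + 1, len(labels))]

    def hists_of(ridges: dict[str, Ridge]) -> dict[tuple[str, str], PhaseHistogram]:
        out = {}
        for a, b in pairs:
            times, dphi, n_total = phase_difference(ridges[a], ridges[b], method)
            out[(a, b)] = phase_histogram(dphi, n_bins, lock_tol, n_total, (a, b))
        return out

    curve = contrast_curve(hists_of(test_ridges), hists_of(rest_ridges))
    return detect_connected_pairs(curve, knee_factor)


def export_network(curve: ContrastCurve, path: str | Path,
                   labels: list[str] | None = None) -> None:
    """Write the detected network as a JSON edge list or CSV adjacency table."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        idx = {p: i for i, p in enumerate(curve.pairs)}
        payload = {
            "identifiable": curve.identifiable,
            "knee_index": curve.knee_index,
            "edges": [
                {"a": a, "b": b, "D": float(curve.D[idx[(a, b)]])}
                for a, b in curve.connected
            ],
        }
        path.write_text(json.dumps(payload, indent=1))
    else:
        if labels is None:
            labels = sorted({c for p in curve.pairs for c in p})
        adj = pd.DataFrame(0, index=labels, columns=labels, dtype=int)
        for a, b in curve.connected:
            adj.loc[a, b] = adj.loc[b, a] = 1
        adj.to_csv(path)
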