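"""Diagnostic plots: segmented traces, threshold scans, contrast curves."""

from __future__ import annotations

import numpy as np

from .connectivity import ContrastCurve, PhaseHistogram
from .io import IntervalSet, Recording
from .segmentation import ThresholdScan

__all__ = [
    "plot_segmentation",
    "plot_threshold_scan",
    "plot_contrast_curve",
    "plot_phase_histogram",
]


def _axes(ax):
    if ax is None:
        import matplotlib.pyplot as plt
        _, ax = plt.subplots()
    return ax


def plot_segmentation(rec: Recording, hits: IntervalSet, channels=None, ax=None):
    """Stacked channel traces with retained intervals shaded."""
    ax = _axes(ax)
    labels = channels or rec.labels
    offset = 0.0
    step = 3 * np.median([rec.channel(l).std() for l in labels]) or 1.0
    for lbl in labels:
        x = rec.channel(lbl)
        ax.plot(rec.times, x + offset, lw=0.4, label=lbl)
        offset += 2 * step
    for iv in hits:
        ax.axvspan(iv.start, iv.end, color="tab:red", alpha=0.2)
    ax.set_xlabel("time, s")
    ax.set_yticks([])
    return ax


def plot_threshold_scan(scan: ThresholdScan, ax=None):
    """Segment count versus candidate threshold, with the chosen knee."""
    ax = _axes(ax)
    ax.plot(scan.thresholds, scan.seg_counts, lw=0.6, label="segments")
    ax.plot(scan.thresholds, scan.smoothed, lw=1.2, label="smoothed")
    ax.axvline(scan.chosen, color="tab:red", ls="--",
               label=f"Tr = {scan.chosen:.3g}")
    ax.set_xlabel(r"threshold $T_r$, $\mu V^2$/Hz")
    ax.set_ylabel("ridge segments")
    ax.legend()
    return ax


def plot_contrast_curve(curve: ContrastCurve, ax=None):
    """Sorted contrast D and its derivative, with the knee if detected."""
    ax = _axes(ax)
    n = np.arange(len(curve.pairs))
    ax.plot(n, curve.D, label="D (sorted)")
    ax.plot(n, curve.deriv, label="derivative")
    if curve.knee_index is not None:
        ax.axvline(curve.knee_index, color="tab:red", ls="--", label="knee")
    ax.set_xlabel("pair rank")
    ax.set_ylabel("D = A - B")
    ax.legend()
    return ax


def plot_phase_histogram(hist: PhaseHistogram, ax=None):
    """Normalized phase-difference histogram for one channel pair."""
    ax = _axes(ax)
    centers = 0.5 * (hist.bin_edges[:-1] + hist.bin_edges[1:])
    ax.bar(centers, hist.portions, width=np.diff(hist.bin_edges), align="center")
    ax.set_xlabel(r"$\Delta\Phi$, rad")
    ax.set_ylabel(r"portion $\rho$")
    ax.set_title("-".join(hist.pair))
    return ax
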