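"""Recording and interval containers with CSV/EDF persistence.

EEG comes to this package either as EDF/EDF+ (the de-facto clinical
container) or as a delimited-text matrix with one column per channel.
Amplitudes are kept in microvolts throughout; intervals are half-open
``[start, end)`` in seconds from the start of the recording.
"""

from __future__ import annotations

import json
import struct
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Recording",
    "Interval",
    "IntervalSet",
    "read_recording",
    "write_recording",
    "read_intervals",
    "write_intervals",
]


@dataclass
class Recording:
    """Multichannel EEG recording.

    Parameters
    ----------
    samples : ndarray, shape (n_channels, n_times)
        Amplitudes in microvolts.
    fs : float
        Sampling rate in Hz.
    labels : list of str
        Channel names (10-20 montage labels for clinical data).
    start_time : float
        Offset of the first sample in seconds (default 0).
    """

    samples: np.ndarray
    fs: float
    labels: list[str]
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if len(self.labels) != self.samples.shape[0]:
            raise ValueError(
                f"{len(self.labels)} labels for {self.samples.shape[0]} channels"
            )
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("channel labels must be unique")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_times(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.n_times / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.n_times) / self.fs

    def channel(self, label: str) -> np.ndarray:
        """Return one channel's samples by its montage label."""
        try:
            idx = self.labels.index(label)
        except ValueError:
            raise KeyError(f"no channel {label!r}; have {self.labels}") from None
        return self.samples[idx]

    def copy_with(self, samples: np.ndarray) -> "Recording":
        return replace(self, samples=np.asarray(samples, dtype=float))


@dataclass(frozen=True, order=True)
class Interval:
    """Half-open time interval ``[start, end)`` in seconds."""

    start: float
    end: float
    label: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"need 0 <= start < end, got [{self.start}, {self.end})")

    @property
    def duration(self) -> float:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return self.start < other.end and other.start < self.end


@dataclass
class IntervalSet:
    """Ordered collection of half-open intervals with a provenance tag.

    ``normalize`` sorts by start and coalesces overlapping or touching
    intervals that carry the same label; it is idempotent and
    order-independent, so downstream interval arithmetic never sees an
    ambiguous representation.
    """

    intervals: list[Interval] = field(default_factory=list)
    channel_or_pair: str | None = None

    def __post_init__(self) -> None:
        self.intervals = sorted(self.intervals)

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def __eq__(self, other) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return self.intervals == other.intervals

    @property
    def total_duration(self) -> float:
        """Summed duration of the union of all intervals (label-blind)."""
        total = 0.0
        prev_end = -np.inf
        for iv in sorted(self.intervals):
            start = max(iv.start, prev_end)
            if iv.end > start:
                total += iv.end - start
                prev_end = iv.end
        return total

    def normalize(self) -> "IntervalSet":
        """Coalesce overlapping/touching same-label intervals."""
        by_label: dict[str, list[Interval]] = {}
        for iv in self.intervals:
            by_label.setdefault(iv.label, []).append(iv)
        merged: list[Interval] = []
        for label, ivs in by_label.items():
            ivs.sort()
            cur_start, cur_end = ivs[0].start, ivs[0].end
            for iv in ivs[1:]:
                if iv.start <= cur_end:
                    cur_end = max(cur_end, iv.end)
                else:
                    merged.append(Interval(cur_start, cur_end, label))
                    cur_start, cur_end = iv.start, iv.end
            merged.append(Interval(cur_start, cur_end, label))
        return IntervalSet(merged, self.channel_or_pair)


# ---------------------------------------------------------------------------
# CSV recording I/O

def _read_csv_recording(path: Path, fs: float | None) -> Recording:
    if fs is None:
        sidecar = path.with_suffix(".json")
        if sidecar.exists():
            fs = json.loads(sidecar.read_text()).get("fs")
        if fs is None:
            raise ValueError(
                "sampling rate not given; pass fs= or provide a JSON sidecar with an 'fs' key"
            )
    df = pd.read_csv(path)
    if df.isna().any().any():
        raise ValueError(f"{path}: channels have mismatched lengths or missing values")
    return Recording(df.to_numpy().T, float(fs), [str(c) for c in df.columns])


def _write_csv_recording(rec: Recording, path: Path) -> None:
    pd.DataFrame(rec.samples.T, columns=rec.labels).to_csv(path, index=False)
    path.with_suffix(".json").write_text(json.dumps({"fs": rec.fs}))


# ---------------------------------------------------------------------------
# EDF I/O.  EDF is a fixed-layout 16-bit format: a 256-byte global header,
# 256 bytes per signal, then data records of little-endian int16 scaled
# between the declared physical and digital extrema.  Only the subset needed
# for plain continuous EEG is implemented (equal rates, one montage).

_EDF_DIGITAL_MIN, _EDF_DIGITAL_MAX = -32768, 32767


def _edf_field(value: str, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def _write_edf_recording(rec: Recording, path: Path) -> None:
    fs = rec.fs
    spr = fs  # samples per 1 s data record
    if abs(spr - round(spr)) > 1e-9:
        raise ValueError("EDF export requires an integer sampling rate")
    spr = int(round(spr))
    n_rec = int(np.ceil(rec.n_times / spr))
    ns = rec.n_channels

    data = np.zeros((ns, n_rec * spr))
    data[:, : rec.n_times] = rec.samples
    phys_min = np.minimum(data.min(axis=1), -1.0)
    phys_max = np.maximum(data.max(axis=1), 1.0)

    hdr = b"".join([
        _edf_field("0", 8),
        _edf_field("X X X X", 80),          # local patient id (anonymous)
        _edf_field("Startdate X X X X", 80),
        _edf_field("01.01.00", 8),
        _edf_field("00.00.00", 8),
        _edf_field(str(256 * (ns + 1)), 8),
        _edf_field("", 44),
        _edf_field(str(n_rec), 8),
        _edf_field("1", 8),                 # record duration, seconds
        _edf_field(str(ns), 4),
    ])
    per_sig = b"".join([
        b"".join(_edf_field(lbl, 16) for lbl in rec.labels),
        b"".join(_edf_field("", 80) for _ in range(ns)),
        b"".join(_edf_field("uV", 8) for _ in range(ns)),
        b"".join(_edf_field(f"{phys_min[i]:.8g}"[:8], 8) for i in range(ns)),
        b"".join(_edf_field(f"{phys_max[i]:.8g}"[:8], 8) for i in range(ns)),
        b"".join(_edf_field(str(_EDF_DIGITAL_MIN), 8) for _ in range(ns)),
        b"".join(_edf_field(str(_EDF_DIGITAL_MAX), 8) for _ in range(ns)),
        b"".join(_edf_field("", 80) for _ in range(ns)),
        b"".join(_edf_field(str(spr), 8) for _ in range(ns)),
        b"".join(_edf_field("", 32) for _ in range(ns)),
    ])

    # re-read the 8-char physical extrema so scaling matches what the header says
    pmin = np.array([float(f"{phys_min[i]:.8g}"[:8]) for i in range(ns)])
    pmax = np.array([float(f"{phys_max[i]:.8g}"[:8]) for i in range(ns)])
    gain = (_EDF_DIGITAL_MAX - _EDF_DIGITAL_MIN) / (pmax - pmin)
    digital = np.round(
        (data - pmin[:, None]) * gain[:, None] + _EDF_DIGITAL_MIN
    ).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(hdr + per_sig)
        for r in range(n_rec):
            fh.write(digital[:, r * spr : (r + 1) * spr].tobytes())


def _read_edf_recording(path: Path) -> Recording:
    with open(path, "rb") as fh:
        head = fh.read(256)
        if len(head) < 256:
            raise ValueError(f"{path}: truncated EDF header")
        n_rec = int(head[236:244])
        rec_dur = float(head[244:252])
        ns = int(head[252:256])
        sig = fh.read(256 * ns)
        labels = [sig[16 * i : 16 * (i + 1)].decode("ascii").strip() for i in range(ns)]
        off = 16 * ns + 80 * ns + 8 * ns
        pmin = np.array([float(sig[off + 8 * i : off + 8 * (i + 1)]) for i in range(ns)])
        off += 8 * ns
        pmax = np.array([float(sig[off + 8 * i : off + 8 * (i + 1)]) for i in range(ns)])
        off += 8 * ns
        dmin = np.array([float(sig[off + 8 * i : off + 8 * (i + 1)]) for i in range(ns)])
        off += 8 * ns
        dmax = np.array([float(sig[off + 8 * i : off + 8 * (i + 1)]) for i in range(ns)])
        off += 8 * ns + 80 * ns
        spr = np.array([int(sig[off + 8 * i : off + 8 * (i + 1)]) for i in range(ns)])
        payload = fh.read()

    if len(set(spr)) != 1:
        raise ValueError("mixed per-signal sampling rates are not supported")
    spr0 = int(spr[0])
    fs = spr0 / rec_dur
    expect = 2 * ns * spr0 * n_rec
    if len(payload) < expect:
        raise ValueError(f"{path}: data area shorter than header promises")
    digital = np.frombuffer(payload[:expect], dtype="<i2").reshape(n_rec, ns, spr0)
    digital = np.transpose(digital, (1, 0, 2)).reshape(ns, n_rec * spr0)
    gain = (pmax - pmin) / (dmax - dmin)
    samples = (digital - dmin[:, None]) * gain[:, None] + pmin[:, None]
    return Recording(samples, fs, labels)


def read_recording(path: str | Path, format: str | None = None, fs: float | None = None) -> Recording:
    """Read an EEG recording from EDF or a CSV matrix.

    ``format`` defaults by extension.  For CSV, the first row holds channel
    labels and ``fs`` comes from the argument or a ``.json`` sidecar.
    """
    path = Path(path)
    fmt = format or ("edf" if path.suffix.lower() == ".edf" else "csv")
    if fmt == "edf":
        return _read_edf_recording(path)
    if fmt == "csv":
        return _read_csv_recording(path, fs)
    raise ValueError(f"unknown format {fmt!r}")


def write_recording(rec: Recording, path: str | Path, format: str | None = None) -> None:
    """Write a recording as EDF or a CSV matrix (with an fs sidecar)."""
    path = Path(path)
    fmt = format or ("edf" if path.suffix.lower() == ".edf" else "csv")
    if fmt == "edf":
        _write_edf_recording(rec, path)
    elif fmt == "csv":
        _write_csv_recording(rec, path)
    else:
        raise ValueError(f"unknown format {fmt!r}")


# ---------------------------------------------------------------------------
# Interval persistence

def write_intervals(ivset: IntervalSet, path: str | Path) -> None:
    """Export intervals as ``start_s,end_s,label,owner`` CSV or as JSON."""
    path = Path(path)
    rows = [
        {"start_s": iv.start, "end_s": iv.end, "label": iv.label,
         "owner": ivset.channel_or_pair or ""}
        for iv in ivset
    ]
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(rows, indent=1))
    else:
        pd.DataFrame(rows, columns=["start_s", "end_s", "label", "owner"]).to_csv(
            path, index=False
        )


def read_intervals(path: str | Path) -> IntervalSet:
    path = Path(path)
    if path.suffix.lower() == ".json":
        rows = json.loads(path.read_text())
    else:
        rows = pd.read_csv(path, keep_default_na=False).to_dict("records")
    ivs = [Interval(float(r["start_s"]), float(r["end_s"]), str(r.get("label", ""))) for r in rows]
    owner = str(rows[0].get("owner", "")) if rows else None
    return IntervalSet(ivs, owner or None)
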