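"""Event-aligned epoch extraction, per-window z-scoring and binned AUC.

Processed photometry traces are cut into windows surrounding behavioral
event onsets (nose poke, cue, reward delivery, tail lift, ...), optionally
z-scored against each window's own mean and standard deviation, averaged
across trials, and summarized as signed trapezoidal area under the curve
over fixed-width time bins around the event.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .photometry import ProcessedTrace
from .simulate import EventSchedule

__all__ = [
    "EpochMatrix",
    "AucBins",
    "extract_epochs",
    "auc_bins",
    "summarize_window",
    "count_events",
]


@dataclass
class EpochMatrix:
    window: tuple               # (pre s, post s) around onset
    time: np.ndarray            # relative time axis, shared by all rows
    rows: np.ndarray            # events x samples
    zscored: bool
    event_label: str = ""
    n_excluded_bounds: int = 0
    n_excluded_flat: int = 0

    @property
    def mean(self) -> np.ndarray:
        return self.rows.mean(axis=0)

    @property
    def sem(self) -> np.ndarray:
        n = self.rows.shape[0]
        return self.rows.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros(self.rows.shape[1])


@dataclass
class AucBins:
    bin_width: float
    bins: list                  # (start s, end s, auc) relative to origin
    partial_final: bool = False

    @property
    def values(self) -> np.ndarray:
        return np.array([b[2] for b in self.bins])


def _trace_parts(trace):
    if isinstance(trace, ProcessedTrace):
        return trace.t, trace.value
    t, v = trace
    return np.asarray(t, float), np.asarray(v, float)


def extract_epochs(
    trace,
    event_times,
    window: tuple,
    zscore_per_epoch: bool = True,
    event_label: str = "",
) -> EpochMatrix:
    """Cut a processed trace into windows of (pre, post) seconds around
    each event onset.

    Events whose window falls outside the recording are excluded and
    counted; when z-scoring, rows with zero variance are likewise excluded
    with a warning.  Rows share a common relative time grid at the trace's
    sampling rate.
    """
    t, v = _trace_parts(trace)
    pre, post = window
    if pre < 0 or post < 0:
        raise ValueError("window extents must be non-negative")
    rate = 1.0 / float(np.median(np.diff(t)))
    n_pre = int(round(pre * rate))
    n_post = int(round(post * rate))
    rows, excluded = [], 0
    for ev in np.atleast_1d(np.asarray(event_times, float)):
        i = int(np.argmin(np.abs(t - ev)))
        lo, hi = i - n_pre, i + n_post     # half-open [onset-pre, onset+post)
        if lo < 0 or hi > t.size:
            excluded += 1
            continue
        rows.append(v[lo:hi])
    if not rows:
        raise ValueError("no events fall inside the recording bounds")
    rows = np.asarray(rows)
    flat = 0
    if zscore_per_epoch:
        mu = rows.mean(axis=1, keepdims=True)
        sd = rows.std(axis=1, keepdims=True)
        ok = sd[:, 0] > 0
        flat = int((~ok).sum())
        if flat:
            warnings.warn(f"{flat} zero-variance epoch(s) excluded from z-scoring")
        rows = (rows[ok] - mu[ok]) / sd[ok]
        if rows.shape[0] == 0:
            raise ValueError("every epoch had zero variance")
    rel = (np.arange(n_pre + n_post) - n_pre) / rate
    return EpochMatrix(window=(pre, post), time=rel, rows=rows,
                       zscored=zscore_per_epoch, event_label=event_label,
                       n_excluded_bounds=excluded, n_excluded_flat=flat)


def auc_bins(values: np.ndarray, rate: float, bin_width: float = 5.0,
             origin: float = 0.0, t: np.ndarray | None = None) -> AucBins:
    """Signed trapezoidal AUC over contiguous bins of bin_width seconds.

    Bin edges are anchored at `origin` on the relative time axis (event
    onset) and extend over the whole series in both directions.  Edges are
    snapped to the sample grid so the AUCs of adjacent bins add exactly to
    the integral over their union; a final partial bin is flagged.
    """
    values = np.asarray(values, float)
    if t is None:
        t = np.arange(values.size) / rate
    else:
        t = np.asarray(t, float)
    step = int(round(bin_width * rate))
    if step < 1 or values.size < step + 1:
        raise ValueError("series shorter than one bin")
    i0 = int(np.argmin(np.abs(t - origin)))
    # bin edges on the sample grid, anchored at the origin sample
    first = i0 % step
    edges = list(range(first, values.size, step))
    if not edges or edges[0] != 0:
        edges = [0] + edges
    if edges[-1] != values.size - 1:
        edges.append(values.size - 1)
    bins = []
    partial = False
    for lo, hi in zip(edges[:-1], edges[1:]):
        auc = float(np.trapezoid(values[lo:hi + 1], t[lo:hi + 1]))
        if (hi - lo) != step:
            partial = True
        bins.append((float(t[lo] - t[i0]), float(t[hi] - t[i0]), auc))
    return AucBins(bin_width=bin_width, bins=bins, partial_final=partial)


def summarize_window(trace, window: tuple) -> float:
    """Arithmetic mean of a processed trace over (start s, end s)."""
    t, v = _trace_parts(trace)
    start, end = window
    idx = (t >= start) & (t < end)
    if not idx.any():
        raise ValueError("summary window contains no samples")
    return float(v[idx].mean())


def count_events(schedule: EventSchedule, label: str,
                 window: tuple | None = None) -> int:
    """Number of events with the given label whose onset falls in window."""
    times = schedule.times(label)
    if window is None:
        return int(times.size)
    start, end = window
    return int(((times >= start) & (times < end)).sum())
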