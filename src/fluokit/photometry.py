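"""Fiber-photometry preprocessing: three isosbestic-correction pipelines.

Two-channel recordings pair a ligand-sensitive excitation channel with an
isosbestic control channel that shares bleaching and motion artifacts but
not the ligand signal.  Three preprocessing variants are provided, each
matched to a recording context:

``arc``
    Downsample to 1 Hz, trim the first and last seconds, fit a power-like
    bleaching baseline F0(t) = a*(t+t0)^(-b) + c per channel on the
    pre-injection period (falling back to the baseline median when no
    decay can be fitted), form ΔF/F₀ per channel against that baseline,
    and subtract the control ΔF/F₀ from the signal ΔF/F₀.

``baseline_lls``
    For long pharmacology/chemogenetics recordings: linear least-squares
    (LLS) fit of the signal on the control over the pre-injection baseline,
    subtract the fitted control, downsample by a factor of 300, smooth over
    a rolling 10-s window, and z-score against the baseline period.

``session_lls``
    For event-rich behavioral sessions: divide each channel by a fitted
    fourth-degree polynomial (bleach detrend), LLS over the whole session,
    divide the signal by the fitted control, downsample by a factor of 100
    and smooth over a rolling 1-s window.  Epoch z-scoring happens
    downstream.

Every ProcessedTrace records the ordered steps applied; `replay` re-runs a
trace's provenance on the raw recording and must reproduce it exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.stats import linregress

from .simulate import TwoChannelRecording

__all__ = [
    "LlsFit",
    "ProcessedTrace",
    "fit_lls",
    "fit_powerlike_baseline",
    "preprocess_arc",
    "preprocess_baseline_lls",
    "preprocess_session_lls",
    "replay",
    "downsample_block",
    "downsample_to_1hz",
    "rolling_smooth",
]


@dataclass
class LlsFit:
    slope: float
    intercept: float
    window: tuple | str         # (start s, end s) or 'session'
    r_squared: float

    def predict(self, control: np.ndarray) -> np.ndarray:
        return self.slope * np.asarray(control, float) + self.intercept


@dataclass
class ProcessedTrace:
    t: np.ndarray
    value: np.ndarray
    variant: str                # 'arc' | 'baseline_lls' | 'session_lls'
    unit: str                   # 'dff' | 'zscore' | 'ratio'
    baseline_window: tuple | None
    provenance: list = field(default_factory=list)

    @property
    def rate(self) -> float:
        return 1.0 / float(np.median(np.diff(self.t)))


# ---------------------------------------------------------------------------
# shared primitives
# ---------------------------------------------------------------------------

def fit_lls(control: np.ndarray, signal: np.ndarray,
            mask: np.ndarray | None = None,
            window: tuple | str = "session") -> LlsFit:
    """Ordinary least squares of the signal channel on the control channel."""
    control = np.asarray(control, float)
    signal = np.asarray(signal, float)
    if mask is not None:
        c, s = control[mask], signal[mask]
    else:
        c, s = control, signal
    if c.size < 2:
        raise ValueError("need at least 2 samples for the LLS fit")
    if np.ptp(c) == 0:
        raise ValueError("control channel is constant over the fit window")
    res = linregress(c, s)
    return LlsFit(float(res.slope), float(res.intercept), window,
                  float(res.rvalue ** 2))


def downsample_block(x: np.ndarray, factor: int) -> np.ndarray:
    """Non-overlapping block means; a trailing partial block is dropped."""
    if factor < 1:
        raise ValueError("factor must be >= 1")
    x = np.asarray(x, float)
    n = (x.size // factor) * factor
    if n == 0:
        raise ValueError("trace shorter than one downsampling block")
    return x[:n].reshape(-1, factor).mean(axis=1)


def downsample_to_1hz(x: np.ndarray, t: np.ndarray):
    """Block-mean the samples of each whole second; returns (t_1hz, x_1hz)
    with times at the bin centers.  Handles non-integer sampling rates."""
    x = np.asarray(x, float)
    sec = np.floor(np.asarray(t, float)).astype(np.int64)
    sec -= sec[0]
    counts = np.bincount(sec)
    sums = np.bincount(sec, weights=x)
    keep = counts > 0
    x1 = sums[keep] / counts[keep]
    t1 = np.flatnonzero(keep).astype(float) + 0.5
    return t1, x1


def rolling_smooth(x: np.ndarray, window_samples: int) -> np.ndarray:
    """Centered moving average with shrink-to-valid edges."""
    if window_samples <= 1:
        return np.asarray(x, float).copy()
    return (
        pd.Series(np.asarray(x, float))
        .rolling(window_samples, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )


# ---------------------------------------------------------------------------
# power-like bleaching baseline (ARC pipeline)
# ---------------------------------------------------------------------------

def _powerlike(t, a, b, t0, c):
    return a * (t + t0) ** (-b) + c


def fit_powerlike_baseline(trace: np.ndarray, t: np.ndarray,
                           baseline_window: tuple):
    """Fit F0(t) = a*(t+t0)^(-b) + c (a, b, t0 > 0) on the baseline window.

    Returns (f0_curve over the whole trace, params, success).  A window
    without decay (non-negative trend) or a failed solve reports
    success=False with a None curve; the caller substitutes the baseline
    median per the pipeline's fallback rule.
    """
    trace = np.asarray(trace, float)
    t = np.asarray(t, float)
    b0, b1 = baseline_window
    idx = (t >= b0) & (t < b1)
    if idx.sum() < 30:
        raise ValueError("need at least 30 baseline samples for the power-like fit")
    tw, yw = t[idx], trace[idx]
    trend = linregress(tw, yw)
    if trend.slope >= 0:
        return None, None, False      # no decay to model
    p0 = (max(np.ptp(yw), 1e-9), 0.3, 10.0, float(yw.min()))
    try:
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                _powerlike, tw, yw, p0=p0, maxfev=20000,
                bounds=([0.0, 1e-6, 1e-6, -np.inf], [np.inf, 10.0, np.inf, np.inf]),
            )
    except (RuntimeError, ValueError):
        return None, None, False
    curve = _powerlike(t, *popt)
    if np.any(curve <= 0):
        return None, None, False
    return curve, tuple(float(p) for p in popt), True


# ---------------------------------------------------------------------------
# pipelines
# ---------------------------------------------------------------------------

def _injection_time(rec: TwoChannelRecording) -> float:
    times = rec.events.times("injection")
    if times.size == 0:
        times = rec.events.times("cno")
    if times.size == 0:
        raise ValueError("recording has no injection/cno baseline marker")
    return float(times[0])


def preprocess_arc(rec: TwoChannelRecording, trim_s: float = 1.0) -> ProcessedTrace:
    """ΔF/F₀(signal) − ΔF/F₀(control) with a power-like bleaching baseline."""
    if rec.t[-1] <= 2 * trim_s:
        raise ValueError("recording shorter than twice the trim length")
    inj = _injection_time(rec)
    baseline_window = (trim_s, inj)

    channels = {}
    t1 = None
    for name, raw in (("signal", rec.signal), ("control", rec.control)):
        t1, x1 = downsample_to_1hz(raw, rec.t)
        keep = (t1 >= trim_s) & (t1 <= t1[-1] - trim_s)
        t1k, x1k = t1[keep], x1[keep]
        base_idx = (t1k >= baseline_window[0]) & (t1k < baseline_window[1])
        # normalize by the baseline median before fitting so the baseline
        # model (and hence dF/F0) is exactly invariant to channel gain
        med = np.median(x1k[base_idx])
        if med <= 0:
            raise ValueError(f"{name} channel has non-positive baseline median")
        x1n = x1k / med
        f0, params, ok = fit_powerlike_baseline(x1n, t1k, baseline_window)
        if not ok:
            f0 = np.full_like(x1n, np.median(x1n[base_idx]))
        channels[name] = (x1n - f0) / f0
        t1 = t1k
    out = channels["signal"] - channels["control"]
    prov = [
        {"variant": "arc", "kwargs": {"trim_s": trim_s}},
        {"step": "downsample_to_1hz"},
        {"step": "trim", "trim_s": trim_s},
        {"step": "powerlike_dff", "baseline_window": baseline_window},
        {"step": "subtract_control_dff"},
    ]
    return ProcessedTrace(t=t1, value=out, variant="arc", unit="dff",
                          baseline_window=baseline_window, provenance=prov)


def preprocess_baseline_lls(
    rec: TwoChannelRecording,
    baseline_window: tuple | None = None,
    down: int = 300,
    smooth_s: float = 10.0,
) -> ProcessedTrace:
    """Baseline-fitted LLS subtraction, downsample, smooth, z-score."""
    if baseline_window is None:
        baseline_window = (0.0, _injection_time(rec))
    b0, b1 = baseline_window
    mask = (rec.t >= b0) & (rec.t < b1)
    if mask.sum() < 2:
        raise ValueError("baseline window too short for the LLS fit")
    lls = fit_lls(rec.control, rec.signal, mask=mask, window=baseline_window)
    corrected = rec.signal - lls.predict(rec.control)

    t_ds = downsample_block(rec.t, down)
    x_ds = downsample_block(corrected, down)
    rate_ds = rec.rate / down
    win = max(int(round(smooth_s * rate_ds)), 1)
    x_sm = rolling_smooth(x_ds, win)

    base = (t_ds >= b0) & (t_ds < b1)
    if not base.any():
        raise ValueError("baseline window empty after downsampling")
    mu, sd = x_sm[base].mean(), x_sm[base].std()
    if sd == 0:
        raise ValueError("baseline has zero variance; cannot z-score")
    z = (x_sm - mu) / sd
    prov = [
        {"variant": "baseline_lls",
         "kwargs": {"baseline_window": baseline_window, "down": down,
                    "smooth_s": smooth_s}},
        {"step": "lls_subtract", "slope": lls.slope, "intercept": lls.intercept},
        {"step": "downsample_block", "factor": down},
        {"step": "rolling_smooth", "window_samples": win},
        {"step": "zscore_baseline", "mean": float(mu), "sd": float(sd)},
    ]
    return ProcessedTrace(t=t_ds, value=z, variant="baseline_lls", unit="zscore",
                          baseline_window=baseline_window, provenance=prov)


def preprocess_session_lls(
    rec: TwoChannelRecording,
    poly_degree: int = 4,
    down: int = 100,
    smooth_s: float = 1.0,
) -> ProcessedTrace:
    """Polynomial bleach detrend, whole-session LLS ratio, downsample, smooth."""
    if rec.t.size < 10 * (poly_degree + 1):
        raise ValueError("recording too short for the polynomial detrend")
    # fit in a rescaled time variable for conditioning
    ts = rec.t / max(rec.t[-1], 1.0)
    detrended = {}
    for name, raw in (("signal", rec.signal), ("control", rec.control)):
        coeffs = np.polyfit(ts, raw, poly_degree)
        curve = np.polyval(coeffs, ts)
        if np.any(curve <= 0):
            raise ValueError(f"polynomial detrend of {name} channel crosses zero")
        detrended[name] = raw / curve
    lls = fit_lls(detrended["control"], detrended["signal"], window="session")
    fitted = lls.predict(detrended["control"])
    if np.any(fitted <= 0):
        raise ValueError("fitted control crosses zero; cannot divide")
    ratio = detrended["signal"] / fitted

    t_ds = downsample_block(rec.t, down)
    x_ds = downsample_block(ratio, down)
    rate_ds = rec.rate / down
    win = max(int(round(smooth_s * rate_ds)), 1)
    x_sm = rolling_smooth(x_ds, win)
    prov = [
        {"variant": "session_lls",
         "kwargs": {"poly_degree": poly_degree, "down": down,
                    "smooth_s": smooth_s}},
        {"step": "polynomial_detrend", "degree": poly_degree},
        {"step": "lls_divide", "slope": lls.slope, "intercept": lls.intercept},
        {"step": "downsample_block", "factor": down},
        {"step": "rolling_smooth", "window_samples": win},
    ]
    return ProcessedTrace(t=t_ds, value=x_sm, variant="session_lls", unit="ratio",
                          baseline_window=None, provenance=prov)


_VARIANTS = {
    "arc": preprocess_arc,
    "baseline_lls": preprocess_baseline_lls,
    "session_lls": preprocess_session_lls,
}


def replay(rec: TwoChannelRecording, provenance: list) -> ProcessedTrace:
    """Re-run a ProcessedTrace's recorded pipeline on the raw recording."""
    head = provenance[0]
    fn = _VARIANTS[head["variant"]]
    return fn(rec, **head["kwargs"])
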