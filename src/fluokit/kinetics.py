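"""Mono-exponential kinetics: activation/decay time constants and gating.

Sensor activation after a ligand step and the return to baseline after
wash-off are both well described by single exponentials,

    association: y(t) = offset + amplitude * (1 - exp(-t / tau))
    decay:       y(t) = offset + amplitude * exp(-t / tau)

Bolus-application experiments are gated on how fast the ligand actually
arrives: the onset latency of a co-applied inert dye (time to reach 85% of
its plateau) must stay below 50 ms, otherwise diffusion rather than sensor
kinetics dominates the rise and the experiment is excluded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import linregress

from .imaging import RoiMask
from .simulate import PixelStack

__all__ = [
    "ExpFitResult",
    "LatencyGate",
    "onset_latency",
    "fit_mono_exponential",
    "pixelwise_tau_on",
]


@dataclass
class ExpFitResult:
    tau: float                  # s
    amplitude: float
    offset: float
    mode: str                   # 'association' | 'decay'
    rss: float
    converged: bool
    inverted: bool = False      # amplitude sign opposite to the mode's convention


@dataclass
class LatencyGate:
    latency: float              # s (nan when no crossing)
    fraction: float
    max_latency: float
    passed: bool
    reason: str = ""


def onset_latency(
    reference: np.ndarray,
    rate: float,
    fraction: float = 0.85,
    max_latency: float = 0.050,
    application_time: float = 0.0,
) -> LatencyGate:
    """Time for a reference (dye) trace to reach `fraction` of its plateau.

    Baseline is the mean of samples before application_time (the first
    sample when none precede it); plateau is the mean of the final 10% of
    the trace.  The gate passes when the latency is below max_latency.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    y = np.asarray(reference, dtype=float)
    t = np.arange(y.size) / rate
    pre = t < application_time
    baseline = y[pre].mean() if pre.any() else y[0]
    tail = max(y.size // 10, 1)
    plateau = y[-tail:].mean()
    if plateau <= baseline:
        return LatencyGate(float("nan"), fraction, max_latency, False,
                           "no positive excursion above baseline")
    thresh = baseline + fraction * (plateau - baseline)
    start = int(np.searchsorted(t, application_time, side="right"))
    above = np.flatnonzero(y[start:] >= thresh)
    if above.size == 0:
        return LatencyGate(float("nan"), fraction, max_latency, False,
                           "threshold never crossed")
    latency = t[start + above[0]] - application_time
    return LatencyGate(float(latency), fraction, max_latency,
                       latency < max_latency, "")


def _assoc(t, tau, amp, off):
    return off + amp * (1.0 - np.exp(-t / tau))


def _decay(t, tau, amp, off):
    return off + amp * np.exp(-t / tau)


def _log_linear_tau(t, y, mode):
    """Initial tau from a log-linear regression on the deviation from the
    asymptote; falls back to a fifth of the trace duration."""
    if mode == "decay":
        dev = y - y.min()
    else:
        dev = y.max() - y
    pos = dev > 1e-12 * max(dev.max(), 1e-300)
    if pos.sum() >= 3:
        res = linregress(t[pos], np.log(dev[pos]))
        if res.slope < 0:
            return -1.0 / res.slope
    return max((t[-1] - t[0]) / 5.0, 1e-6)


def fit_mono_exponential(trace: np.ndarray, rate: float, mode: str) -> ExpFitResult:
    """Nonlinear least-squares fit of a mono-exponential model.

    Initialization comes from a log-linear regression; tau is bounded by
    ten times the trace duration.  A constant trace or a failed solve
    returns converged=False.
    """
    if mode not in ("association", "decay"):
        raise ValueError("mode must be 'association' or 'decay'")
    y = np.asarray(trace, dtype=float)
    if y.size < 10:
        raise ValueError("need at least 10 samples to fit")
    t = np.arange(y.size) / rate
    if np.ptp(y) == 0:
        return ExpFitResult(float("nan"), 0.0, float(y[0]), mode, 0.0, False)
    model = _assoc if mode == "association" else _decay
    tau0 = min(_log_linear_tau(t, y, mode), 10.0 * t[-1])
    amp0 = (y[-1] - y[0]) if mode == "association" else (y[0] - y[-1])
    off0 = y[0] if mode == "association" else y[-1]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                model, t, y, p0=(tau0, amp0, off0), maxfev=20000,
                bounds=([1e-9, -np.inf, -np.inf], [10.0 * t[-1], np.inf, np.inf]),
            )
    except (RuntimeError, ValueError):
        return ExpFitResult(float("nan"), float("nan"), float("nan"), mode,
                            float("nan"), False)
    tau, amp, off = popt
    rss = float(np.sum((y - model(t, *popt)) ** 2))
    return ExpFitResult(float(tau), float(amp), float(off), mode, rss, True,
                        inverted=amp < 0)


def pixelwise_tau_on(
    stack: PixelStack,
    mask: RoiMask,
    normalize: bool = True,
    fit_start: float = 0.0,
):
    """Fit the association time constant of every masked pixel.

    Each pixel trace (from fit_start onward) is min-max normalized to
    [0, 1] when `normalize` and fit in association mode.  Returns
    (taus, summary) where taus has one entry per masked pixel (nan for
    failed fits) and summary reports mean/sd/n over converged fits.
    """
    sel = np.flatnonzero(mask.selected)
    if sel.size == 0:
        raise ValueError("mask selects no pixels")
    i0 = int(round(fit_start * stack.rate))
    taus = np.full(sel.size, np.nan)
    for k, pix in enumerate(sel):
        y = stack.data[pix, i0:].astype(float)
        if normalize:
            rng_ = np.ptp(y)
            if rng_ == 0:
                continue
            y = (y - y.min()) / rng_
        res = fit_mono_exponential(y, stack.rate, "association")
        if res.converged and res.tau > 0 and not res.inverted:
            taus[k] = res.tau
    ok = ~np.isnan(taus)
    if not ok.any():
        raise ValueError("no converged fits among the masked pixels")
    summary = {
        "mean": float(taus[ok].mean()),
        "sd": float(taus[ok].std(ddof=1)) if ok.sum() > 1 else 0.0,
        "n": int(ok.sum()),
        "n_failed": int((~ok).sum()),
    }
    return taus, summary
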