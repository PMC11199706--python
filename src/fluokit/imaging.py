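"""ΔF/F₀ quantification, ROI selection and bleach correction for imaging.

ΔF/F₀ is the fractional fluorescence change relative to a baseline-period
mean,

    dF/F0(t) = (F_t - F0) / F0,   F0 = mean of F over the baseline window,

the standard readout for GPCR-based fluorescent sensors.  Membrane ROIs are
selected either by Otsu auto-thresholding of the temporal-mean image or by
keeping pixels whose peak ΔF/F₀ reaches a fraction (default 65%) of the
stack-wide peak.  Slow photobleaching in long bath-application recordings
is corrected by fitting a biexponential to the pre-application segment and
dividing it out.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from skimage.filters import threshold_otsu

from .simulate import PixelStack

__all__ = [
    "DffTrace",
    "RoiMask",
    "compute_dff",
    "select_membrane_rois",
    "correct_bleaching_biexp",
    "stepwise_response",
]


@dataclass
class DffTrace:
    """A ΔF/F₀ time series with the baseline that defined it."""

    t: np.ndarray
    dff: np.ndarray
    f0: float
    baseline_window: tuple


@dataclass
class RoiMask:
    selected: np.ndarray        # boolean, one entry per pixel
    method: str                 # 'auto_threshold' | 'dff_fraction'
    threshold_used: float

    @property
    def n_selected(self) -> int:
        return int(self.selected.sum())


def _window_slice(t: np.ndarray, window: tuple) -> np.ndarray:
    start, end = window
    idx = (t >= start) & (t < end)
    return idx


def compute_dff(trace: np.ndarray, baseline_window: tuple, rate: float = 1.0,
                t: np.ndarray | None = None) -> DffTrace:
    """Compute ΔF/F₀ against the mean over baseline_window (seconds)."""
    trace = np.asarray(trace, dtype=float)
    if t is None:
        t = np.arange(trace.size) / rate
    idx = _window_slice(t, baseline_window)
    if not idx.any():
        raise ValueError("baseline window contains no samples")
    f0 = float(trace[idx].mean())
    if f0 <= 0:
        raise ValueError("baseline mean must be positive for dF/F0")
    dff = (trace - f0) / f0
    if np.any(dff < -1):
        warnings.warn("dF/F0 values below -1 clipped; check the baseline window")
        dff = np.clip(dff, -1.0, None)
    return DffTrace(t=t, dff=dff, f0=f0, baseline_window=tuple(baseline_window))


def select_membrane_rois(
    stack: PixelStack,
    method: str = "dff_fraction",
    fraction: float = 0.65,
    baseline_window: tuple | None = None,
) -> RoiMask:
    """Select membrane-corresponding pixels of an imaging stack.

    'dff_fraction' keeps pixels whose peak ΔF/F₀ is at least `fraction`
    (default 0.65) of the stack-wide peak; the baseline for the per-pixel
    ΔF/F₀ defaults to the first 10% of frames.  'auto_threshold' applies
    Otsu's threshold to the temporal-mean image.
    """
    if stack.n_pixels == 0 or stack.n_frames == 0:
        raise ValueError("empty stack")
    if method == "dff_fraction":
        if baseline_window is None:
            baseline_window = (0.0, max(stack.n_frames // 10, 1) / stack.rate)
        t = stack.t
        idx = _window_slice(t, baseline_window)
        f0 = stack.data[:, idx].mean(axis=1)
        if np.any(f0 <= 0):
            raise ValueError("non-positive per-pixel baseline; cannot form dF/F0")
        peak = (stack.data.max(axis=1) - f0) / f0
        thr = fraction * peak.max()
        return RoiMask(selected=peak >= thr, method=method, threshold_used=float(thr))
    if method == "auto_threshold":
        mean_img = stack.data.mean(axis=1)
        if np.ptp(mean_img) == 0:
            warnings.warn("uniform image: auto-threshold returns an empty mask")
            return RoiMask(selected=np.zeros(stack.n_pixels, bool),
                           method=method, threshold_used=float("nan"))
        thr = float(threshold_otsu(mean_img))
        return RoiMask(selected=mean_img > thr, method=method, threshold_used=thr)
    raise ValueError(f"unknown ROI method {method!r}")


def _biexp(t, a1, tau1, a2, tau2, c):
    return a1 * np.exp(-t / tau1) + a2 * np.exp(-t / tau2) + c


def correct_bleaching_biexp(
    trace: np.ndarray,
    pre_application_window: tuple,
    rate: float = 1.0,
    mode: str = "divide",
):
    """Fit a biexponential to the pre-application segment and remove it.

    The fit is extrapolated over the whole trace and divided out (or
    subtracted, mode='subtract'), re-anchored at the first fitted value so
    the corrected pre-application segment is flat at the original level.
    Returns (corrected, report); on non-convergence the original trace is
    returned with report['success'] = False.
    """
    trace = np.asarray(trace, dtype=float)
    t = np.arange(trace.size) / rate
    idx = _window_slice(t, pre_application_window)
    n_pre = int(idx.sum())
    if n_pre < 20:
        raise ValueError("pre-application window too short for a 5-parameter fit")
    tw, yw = t[idx], trace[idx]
    span = max(tw[-1] - tw[0], 1.0 / rate)
    amp0 = max(yw[0] - yw[-1], 1e-6 * abs(yw[0]) + 1e-12)
    p0 = (amp0 / 2, span / 5, amp0 / 2, span, yw[-1])
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                _biexp, tw, yw, p0=p0, maxfev=20000,
                bounds=([0, 1e-9, 0, 1e-9, -np.inf], [np.inf] * 5),
            )
    except (RuntimeError, ValueError):
        return trace.copy(), {"success": False, "params": None, "mode": mode}
    fit = _biexp(t, *popt)
    if mode == "divide":
        if np.any(fit <= 0):
            return trace.copy(), {"success": False, "params": tuple(popt), "mode": mode}
        corrected = trace * (fit[0] / fit)
    elif mode == "subtract":
        corrected = trace - fit + fit[0]
    else:
        raise ValueError("mode must be 'divide' or 'subtract'")
    report = {"success": True, "params": tuple(popt), "mode": mode}
    return corrected, report


def stepwise_response(
    dff: DffTrace,
    application_windows,
    avg_s: float = 180.0,
) -> np.ndarray:
    """Per-step response of a sequential bath-application recording.

    For each application window, the response is the mean ΔF/F₀ over the
    last avg_s seconds of the window minus the mean over the avg_s seconds
    immediately preceding the window (default 3-minute intervals).
    """
    windows = [tuple(w) for w in application_windows]
    for (s1, e1), (s2, e2) in zip(windows, windows[1:]):
        if s2 < e1:
            raise ValueError("application windows must be ordered and non-overlapping")
    out = np.empty(len(windows))
    for i, (start, end) in enumerate(windows):
        if end - start < avg_s:
            raise ValueError(f"window {i} shorter than the {avg_s}-s averaging interval")
        pre = _window_slice(dff.t, (start - avg_s, start))
        late = _window_slice(dff.t, (end - avg_s, end))
        if not pre.any() or not late.any():
            raise ValueError(f"window {i} has empty averaging intervals")
        out[i] = dff.dff[late].mean() - dff.dff[pre].mean()
    return out
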