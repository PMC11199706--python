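"""Concentration-response aggregation and three-parameter Hill fitting.

The response of a saturable sensor to its ligand follows the Hill equation
with a zero lower asymptote (responses are ΔF/F₀ over a ligand-free
baseline):

    R(c) = R_max * c^h / (EC50^h + c^h)

with free parameters {R_max, EC50, h}.  EC50 is reported both in molar and
as pEC50 = -log10(EC50 / 1 M), the field's standard potency scale.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.stats import gmean

__all__ = [
    "HillFitResult",
    "fit_hill3",
    "pec50_from_ec50",
    "normalize_responses",
]


@dataclass
class HillFitResult:
    r_max: float
    ec50: float                 # M
    hill: float
    pec50: float
    covariance: np.ndarray | None
    converged: bool
    message: str = ""


def _hill(logc, r_max, log_ec50, h):
    # parametrized in log10 concentration for conditioning
    return r_max / (1.0 + 10.0 ** (h * (log_ec50 - logc)))


def pec50_from_ec50(ec50: float) -> float:
    """pEC50 = -log10(EC50 in molar)."""
    if ec50 <= 0:
        raise ValueError("ec50 must be positive")
    return -math.log10(ec50)


def fit_hill3(table: pd.DataFrame, pooled: bool = True) -> HillFitResult:
    """Fit the three-parameter Hill equation to a dose-response table.

    Expects columns concentration_M and response (replicate_id optional).
    By default all replicates are pooled into one least-squares problem;
    pooled=False fits the per-concentration replicate means instead.
    Initialization: EC50 at the geometric mean of the tested
    concentrations, h = 1, R_max = max response.  The fit is flagged
    non-converged when the solver fails or the fitted EC50 falls more than
    10x outside the tested concentration range.
    """
    conc = np.asarray(table["concentration_M"], dtype=float)
    resp = np.asarray(table["response"], dtype=float)
    if np.any(conc <= 0):
        raise ValueError("concentrations must be positive")
    uniq = np.unique(conc)
    if uniq.size < 3:
        raise ValueError("need at least 3 distinct concentrations")
    if uniq.max() / uniq.min() < 10.0:
        raise ValueError("concentrations must span at least one decade")
    if not pooled:
        df = pd.DataFrame({"c": conc, "r": resp}).groupby("c", as_index=False).mean()
        conc, resp = df["c"].to_numpy(), df["r"].to_numpy()
    logc = np.log10(conc)
    p0 = (float(resp.max()), float(np.log10(gmean(uniq))), 1.0)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, pcov = curve_fit(
                _hill, logc, resp, p0=p0, maxfev=20000,
                bounds=([0.0, -np.inf, 1e-6], [np.inf, np.inf, 20.0]),
            )
    except (RuntimeError, ValueError) as exc:
        return HillFitResult(float("nan"), float("nan"), float("nan"),
                             float("nan"), None, False, str(exc))
    r_max, log_ec50, h = popt
    ec50 = 10.0 ** log_ec50
    msg = ""
    converged = True
    if ec50 > uniq.max() * 10 or ec50 < uniq.min() / 10:
        converged = False
        msg = "fitted EC50 falls more than 10x outside the tested range"
        warnings.warn(msg)
    return HillFitResult(float(r_max), float(ec50), float(h),
                         pec50_from_ec50(ec50), pcov, converged, msg)


def normalize_responses(table: pd.DataFrame, mode: str = "fitted") -> pd.DataFrame:
    """Scale responses to the plateau (fitted R_max) or the empirical max.

    Returns a copy with the response column divided by the chosen maximum
    and attrs['normalized'] set; the fitted EC50 is invariant to this
    rescaling.
    """
    resp = np.asarray(table["response"], dtype=float)
    if np.all(resp == 0):
        raise ValueError("all responses are zero; nothing to normalize")
    if mode == "fitted":
        fit = fit_hill3(table)
        denom = fit.r_max
        if not np.isfinite(denom) or denom <= 0:
            raise ValueError("fitted maximum unusable for normalization")
    elif mode == "empirical":
        denom = float(resp.max())
    else:
        raise ValueError("mode must be 'fitted' or 'empirical'")
    out = table.copy()
    out["response"] = resp / denom
    out.attrs = dict(table.attrs)
    out.attrs["normalized"] = True
    return out
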