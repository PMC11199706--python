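"""Forward models for sensor fluorescence data with known ground truth.

Every analysis stage in this package can be exercised against the
generators here: a two-state ligand-binding model drives a fluorescence
trace, onto which photobleaching, shared motion artifacts and per-sample
noise are layered to emulate two-channel fiber-photometry sessions,
high-speed confocal line-scan stacks, and dose-response plates.

The binding model is two-state mass action,

    dB/dt = k_on * L(t) * (1 - B) - k_off * B,

whose equilibrium occupancy is the one-site curve L / (L + Kd) with
Kd = k_off / k_on, and whose response to a concentration step is
mono-exponential with rate k_on*L + k_off.  These are exactly the model
classes the downstream fitting routines assume (Hill with slope 1,
mono-exponential association/decay), so parameter recovery is well posed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as _signal

__all__ = [
    "BleachSpec",
    "SensorSimParams",
    "EventSchedule",
    "TwoChannelRecording",
    "PixelStack",
    "simulate_binding_response",
    "ligand_from_schedule",
    "simulate_photometry_session",
    "simulate_linescan",
    "simulate_dose_response",
    "generate_pr_schedule",
    "generate_event_schedule",
]

#: sampling rate (Hz) of the photometry acquisition system being emulated
DEFAULT_PHOTOMETRY_RATE = 1017.25
#: sampling rate (Hz) of the confocal line-scan acquisition being emulated
DEFAULT_LINESCAN_RATE = 800.0


@dataclass(frozen=True)
class BleachSpec:
    """Photobleaching model: a multiplicative decay curve, 1.0 at t=0.

    kind:
        'none'          -- no bleaching
        'power_like'    -- a*(t+t0)**(-b) + c, normalized to 1 at t=0
        'biexponential' -- a1*exp(-t/tau1) + a2*exp(-t/tau2) + c, normalized
        'polynomial'    -- polynomial in t (coeffs, highest power first),
                           normalized; must stay positive over the session
    """

    kind: str = "none"
    params: dict = field(default_factory=dict)

    _KINDS = ("none", "power_like", "biexponential", "polynomial")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown bleach kind {self.kind!r}; expected one of {self._KINDS}")

    def curve(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if self.kind == "none":
            return np.ones_like(t)
        if self.kind == "power_like":
            a = self.params.get("a", 0.4)
            b = self.params.get("b", 0.3)
            t0 = self.params.get("t0", 10.0)
            c = self.params.get("c", 0.6)
            raw = a * (t + t0) ** (-b) + c
        elif self.kind == "biexponential":
            a1 = self.params.get("a1", 0.2)
            tau1 = self.params.get("tau1", 30.0)
            a2 = self.params.get("a2", 0.2)
            tau2 = self.params.get("tau2", 300.0)
            c = self.params.get("c", 0.6)
            raw = a1 * np.exp(-t / tau1) + a2 * np.exp(-t / tau2) + c
        else:  # polynomial
            coeffs = self.params.get("coeffs")
            if coeffs is None:
                # gentle quartic decay over a ~1 h session
                T = max(float(t[-1]), 1.0) if t.size else 1.0
                coeffs = [0.05 / T**4, -0.1 / T**3, 0.0, -0.15 / T, 1.0]
            raw = np.polyval(coeffs, t)
        if np.any(raw <= 0):
            raise ValueError("bleach curve must stay positive over the session")
        return raw / raw[0]


@dataclass(frozen=True)
class SensorSimParams:
    """Ground-truth parameters of the simulated sensor.

    k_on / k_off are chosen so Kd = k_off/k_on = 29 nM, in the range of the
    apparent affinity of high-affinity peptide sensors, and so that a 1 uM
    concentration step relaxes with rate k_on*L + k_off ~ 1 s^-1.  r_max is
    the maximal fractional fluorescence increase (3.88 = 388%).
    """

    k_on: float = 1.0e6        # M^-1 s^-1
    k_off: float = 0.029       # s^-1
    r_max: float = 3.88        # dimensionless (dF/F at saturation)
    f0: float = 100.0          # baseline fluorescence, arbitrary units
    bleach: BleachSpec = field(default_factory=BleachSpec)
    motion_sd: float = 0.0     # shared-artifact amplitude, fraction of f0
    motion_bandwidth: float = 2.0  # Hz, low-pass cutoff of the artifact
    noise_sd: float = 0.0      # per-sample additive noise, fraction of f0
    control_gain: float = 0.7  # control-channel brightness relative to f0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("k_on", "k_off", "f0"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.r_max < 0:
            raise ValueError("r_max must be non-negative")
        if self.motion_sd < 0 or self.noise_sd < 0:
            raise ValueError("noise amplitudes must be non-negative")

    @property
    def kd(self) -> float:
        """Equilibrium dissociation constant k_off / k_on (M)."""
        return self.k_off / self.k_on


@dataclass(frozen=True)
class EventSchedule:
    """Behavioral/pharmacological event log for a session.

    events is a list of (onset time s, label, duration s); onsets are
    strictly increasing and every event ends inside the session.
    """

    events: tuple
    session_length: float
    variant: str = "custom"

    def __post_init__(self) -> None:
        object.__setattr__(self, "events", tuple(tuple(e) for e in self.events))
        times = [e[0] for e in self.events]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("event onsets must be strictly increasing")
        for t, label, dur in self.events:
            if t < 0 or t + dur > self.session_length:
                raise ValueError(f"event {label!r} at {t} s does not fit in session")

    def times(self, label: str) -> np.ndarray:
        return np.array([t for t, lab, _ in self.events if lab == label])

    def labels(self) -> set:
        return {lab for _, lab, _ in self.events}


@dataclass
class TwoChannelRecording:
    """Signal + control photometry channels on a uniform time base."""

    rate: float
    t: np.ndarray
    signal: np.ndarray
    control: np.ndarray
    events: EventSchedule
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (len(self.t) == len(self.signal) == len(self.control)):
            raise ValueError("t, signal and control must have equal length")
        if self.rate <= 0:
            raise ValueError("rate must be positive")


@dataclass
class PixelStack:
    """Imaging movie / line-scan matrix, pixels x frames.

    membrane_mask_truth marks the pixels whose trace carries the sensor
    response (known only in simulation).  reference, when present, is the
    matching matrix for a co-applied inert dye channel used to time the
    arrival of the ligand bolus.
    """

    data: np.ndarray
    rate: float
    membrane_mask_truth: np.ndarray | None = None
    reference: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D pixels x frames matrix")
        if np.any(self.data < 0):
            raise ValueError("fluorescence data must be non-negative")
        if self.rate <= 0:
            raise ValueError("rate must be positive")

    @property
    def n_pixels(self) -> int:
        return self.data.shape[0]

    @property
    def n_frames(self) -> int:
        return self.data.shape[1]

    @property
    def t(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.rate


# ---------------------------------------------------------------------------
# binding model
# ---------------------------------------------------------------------------

def simulate_binding_response(
    params: SensorSimParams,
    ligand: np.ndarray,
    t: np.ndarray,
    b0: float = 0.0,
):
    """Propagate the two-state binding model along a piecewise-constant
    ligand series and return (occupancy, fluorescence).

    The ligand is held constant between consecutive samples, so each
    constant segment is advanced with the exact solution
    B(t) = B_eq + (B_start - B_eq) * exp(-r t), r = k_on*L + k_off,
    B_eq = k_on*L / r.  The result is deterministic and exact on the grid.
    """
    L = np.asarray(ligand, dtype=float)
    t = np.asarray(t, dtype=float)
    if L.shape != t.shape:
        raise ValueError("ligand and t must have the same shape")
    if np.any(L < 0):
        raise ValueError("ligand concentrations must be non-negative")
    if len(t) < 2:
        B = np.full_like(t, b0)
        return B, params.f0 * (1.0 + params.r_max * B)
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
        raise ValueError("t must be uniformly spaced")
    dt = float(dt[0])

    B = np.empty_like(L)
    changes = np.flatnonzero(np.diff(L) != 0) + 1
    starts = np.concatenate(([0], changes))
    ends = np.concatenate((changes, [len(L)]))
    b = float(b0)
    for s, e in zip(starts, ends):
        r = params.k_on * L[s] + params.k_off
        beq = params.k_on * L[s] / r
        rel = np.arange(e - s) * dt
        B[s:e] = beq + (b - beq) * np.exp(-r * rel)
        b = beq + (b - beq) * math.exp(-r * (e - s) * dt)
    np.clip(B, 0.0, 1.0, out=B)
    F = params.f0 * (1.0 + params.r_max * B)
    return B, F


# ---------------------------------------------------------------------------
# event -> ligand mapping
# ---------------------------------------------------------------------------

#: simulator plumbing, not biology: how each event label translates into
#: extracellular ligand at the recording site.  'sustained' events ramp up
#: to amplitude*Kd and stay; 'transient' events add a double-exponential
#: bump of peak amplitude*Kd.  Unlisted labels release nothing.
DEFAULT_LIGAND_EVENTS = {
    "injection": ("sustained", 20.0, 180.0),        # (kind, amp in Kd, tau_rise s)
    "cno": ("sustained", 20.0, 180.0),
    "tail_lift": ("transient", 10.0, 1.0, 10.0),    # (kind, amp, tau_rise, tau_decay)
    "access": ("transient", 10.0, 1.0, 10.0),
    "pellet": ("transient", 10.0, 1.0, 10.0),
}


def ligand_from_schedule(
    schedule: EventSchedule,
    t: np.ndarray,
    kd: float,
    mapping: dict | None = None,
) -> np.ndarray:
    """Build a ligand concentration series (M) from an event schedule."""
    mapping = DEFAULT_LIGAND_EVENTS if mapping is None else mapping
    t = np.asarray(t, dtype=float)
    L = np.zeros_like(t)
    for onset, label, _dur in schedule.events:
        spec = mapping.get(label)
        if spec is None:
            continue
        rel = t - onset
        active = rel >= 0
        if spec[0] == "sustained":
            _, amp, tau_rise = spec
            L[active] += amp * kd * (1.0 - np.exp(-rel[active] / tau_rise))
        elif spec[0] == "transient":
            _, amp, tau_rise, tau_decay = spec
            kern = np.exp(-rel[active] / tau_decay) - np.exp(-rel[active] / tau_rise)
            peak = kern.max() if kern.size else 1.0
            if peak > 0:
                L[active] += amp * kd * kern / peak
        else:
            raise ValueError(f"unknown ligand-event kind {spec[0]!r}")
    return L


def _motion_waveform(rng, n: int, rate: float, sd: float, bandwidth: float) -> np.ndarray:
    """Low-pass-filtered Gaussian noise with standard deviation sd."""
    white = rng.standard_normal(n)
    nyq = rate / 2.0
    if bandwidth < nyq and n > 30:
        b, a = _signal.butter(2, bandwidth / nyq)
        wave = _signal.filtfilt(b, a, white)
    else:
        wave = white
    s = wave.std()
    if s > 0:
        wave = wave * (sd / s)
    return wave


def simulate_photometry_session(
    params: SensorSimParams,
    schedule: EventSchedule,
    rate: float = DEFAULT_PHOTOMETRY_RATE,
    ligand_events: dict | None = None,
) -> TwoChannelRecording:
    """Simulate a two-channel photometry session.

    The ligand-driven component appears only on the signal channel;
    bleaching and the motion artifact are multiplicative and shared by both
    channels (the control channel sees them through its own gain), so an
    ideal isosbestic correction can cancel them.  Additive read noise is
    drawn independently per channel.
    """
    if rate <= 0:
        raise ValueError("rate must be positive")
    n = int(round(schedule.session_length * rate))
    t = np.arange(n) / rate
    L = ligand_from_schedule(schedule, t, params.kd, ligand_events)
    _, F_sig = simulate_binding_response(params, L, t)
    F_ctrl = np.full(n, params.f0 * params.control_gain)

    bleach = params.bleach.curve(t)
    rng = np.random.default_rng(params.seed)
    motion = _motion_waveform(rng, n, rate, params.motion_sd, params.motion_bandwidth)

    sig = F_sig * bleach * (1.0 + motion)
    ctrl = F_ctrl * bleach * (1.0 + motion)
    if params.noise_sd > 0:
        sig = sig + rng.normal(0.0, params.noise_sd * params.f0, n)
        ctrl = ctrl + rng.normal(0.0, params.noise_sd * params.f0, n)

    meta = {
        "signal_nm": 470, "control_nm": 405,
        "seed": params.seed, "kd_M": params.kd, "r_max": params.r_max,
    }
    return TwoChannelRecording(rate=rate, t=t, signal=sig, control=ctrl,
                               events=schedule, meta=meta)


# ---------------------------------------------------------------------------
# line-scan stacks
# ---------------------------------------------------------------------------

def simulate_linescan(
    params: SensorSimParams,
    n_membrane: int,
    n_background: int,
    rate: float = DEFAULT_LINESCAN_RATE,
    tau_true: float = 0.595,
    dye_latency: float = 0.02,
    seed: int | None = None,
    duration: float = 4.0,
    t_on: float = 0.5,
) -> PixelStack:
    """Simulate a high-speed line-scan of membrane + background pixels.

    Membrane pixels follow mono-exponential association with time constant
    tau_true after the bolus arrives at t_on; background pixels are dim and
    unresponsive.  The reference (dye) channel is a smoothed step whose 85%
    rise completes dye_latency seconds after t_on, mimicking the inert
    tracer used to gate experiments on bolus arrival speed.
    """
    if n_membrane < 0 or n_background < 0:
        raise ValueError("pixel counts must be non-negative")
    if tau_true <= 0:
        raise ValueError("tau_true must be positive")
    rng = np.random.default_rng(params.seed if seed is None else seed)
    n_frames = int(round(duration * rate))
    t = np.arange(n_frames) / rate
    rel = np.clip(t - t_on, 0.0, None)
    assoc = np.where(t >= t_on, 1.0 - np.exp(-rel / tau_true), 0.0)

    n_pix = n_membrane + n_background
    data = np.empty((n_pix, n_frames))
    # per-pixel brightness heterogeneity; response shape is shared
    gains = rng.uniform(0.8, 1.2, size=n_pix)
    for i in range(n_membrane):
        data[i] = params.f0 * gains[i] * (1.0 + params.r_max * assoc)
    for j in range(n_membrane, n_pix):
        data[j] = 0.1 * params.f0 * gains[j]
    if params.noise_sd > 0:
        data = data + rng.normal(0.0, params.noise_sd * params.f0, data.shape)
    data = np.clip(data, 0.0, None)

    # dye channel: exponential approach tuned so the 85% crossing sits at
    # exactly dye_latency after t_on
    tau_dye = dye_latency / math.log(1.0 / 0.15) if dye_latency > 0 else 0.0
    if tau_dye > 0:
        dye = np.where(t >= t_on, 1.0 - np.exp(-rel / tau_dye), 0.0)
    else:
        dye = (t >= t_on).astype(float)
    reference = np.tile(50.0 * (0.2 + dye), (max(n_pix, 1), 1))

    truth = np.zeros(n_pix, dtype=bool)
    truth[:n_membrane] = True
    return PixelStack(data=data, rate=rate, membrane_mask_truth=truth,
                      reference=reference)


# ---------------------------------------------------------------------------
# dose-response plates
# ---------------------------------------------------------------------------

#: concentration ladder (M) used in the ex vivo bath-application protocol
EX_VIVO_LADDER = (5e-9, 10e-9, 50e-9, 100e-9, 500e-9, 1e-6, 5e-6, 10e-6)


def simulate_dose_response(
    r_max: float,
    ec50: float,
    hill: float,
    concentrations=EX_VIVO_LADDER,
    replicates: int = 3,
    cv: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate a replicate dose-response table around a Hill curve.

    Each replicate response is Hill(c) * (1 + eps), eps ~ Normal(0, cv).
    Returns a DataFrame with columns concentration_M, response,
    replicate_id.
    """
    if ec50 <= 0 or hill <= 0:
        raise ValueError("ec50 and hill must be positive")
    if cv < 0:
        raise ValueError("cv must be non-negative")
    conc = np.asarray(list(concentrations), dtype=float)
    if conc.size == 0:
        raise ValueError("concentration list must not be empty")
    if np.any(conc <= 0):
        raise ValueError("concentrations must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(replicates):
        ideal = r_max * conc**hill / (ec50**hill + conc**hill)
        eps = rng.normal(0.0, cv, size=conc.size) if cv > 0 else 0.0
        for c, r in zip(conc, ideal * (1.0 + eps)):
            rows.append((c, r, rep))
    df = pd.DataFrame(rows, columns=["concentration_M", "response", "replicate_id"])
    df.attrs["normalized"] = False
    return df


# ---------------------------------------------------------------------------
# behavioral schedules
# ---------------------------------------------------------------------------

def generate_pr_schedule(n_rewards: int) -> list[int]:
    """Nose-poke criteria of the progressive-ratio schedule.

    criterion_i = round_half_away_from_zero(5*e^{i/5} - 5) for i = 1..n,
    giving the sequence 1, 2, 4, 6, 9, 12, ...
    """
    if n_rewards < 0:
        raise ValueError("n_rewards must be non-negative")
    out = []
    for i in range(1, n_rewards + 1):
        x = 5.0 * math.exp(i / 5.0) - 5.0
        out.append(int(math.floor(x + 0.5)))  # half away from zero (x > 0 here)
    return out


def generate_event_schedule(variant: str, seed: int = 0, **params) -> EventSchedule:
    """Build the event schedule for one of the supported session types.

    variant:
        'injection'    -- baseline then a single i.p. injection marker
        'cued_sucrose' -- head-fixed trials: 5-s tone then 5-s spout access,
                          ITI uniform 45-75 s, 5-min flanking baselines
        'tail_lift'    -- 10-s lifts, ITI uniform 120-300 s, 5-min baselines
        'operant_fr'   -- fixed-ratio nose-poke sessions
        'operant_pr'   -- progressive-ratio session (geometric criteria)
    """
    rng = np.random.default_rng(seed)
    if variant == "injection":
        baseline_s = params.get("baseline_s", 300.0)
        session_s = params.get("session_s", 1800.0)
        events = [(baseline_s, "injection", 0.0)]
        return EventSchedule(events, session_s, variant)

    if variant == "cued_sucrose":
        n_trials = params.get("n_trials", 15)
        baseline_s = params.get("baseline_s", 300.0)
        tone_s, access_s = 5.0, 5.0
        events = []
        tcur = baseline_s
        for _ in range(n_trials):
            events.append((tcur, "tone", tone_s))
            events.append((tcur + tone_s, "access", access_s))
            tcur += tone_s + access_s + rng.uniform(45.0, 75.0)
        session_s = tcur + baseline_s
        return EventSchedule(events, session_s, variant)

    if variant == "tail_lift":
        n_trials = params.get("n_trials", 4)
        baseline_s = params.get("baseline_s", 300.0)
        lift_s = 10.0
        events = []
        tcur = baseline_s
        for _ in range(n_trials):
            events.append((tcur, "tail_lift", lift_s))
            tcur += lift_s + rng.uniform(120.0, 300.0)
        session_s = tcur + baseline_s
        return EventSchedule(events, session_s, variant)

    if variant in ("operant_fr", "operant_pr"):
        session_s = params.get("session_s", 3600.0 if variant == "operant_fr" else 7200.0)
        cue_s = 5.0
        if variant == "operant_fr":
            ratio = params.get("ratio", 1)
            criteria = iter(lambda: ratio, 0)  # infinite constant iterator
        else:
            criteria = iter(generate_pr_schedule(params.get("max_rewards", 30)))
        events = []
        tcur = rng.uniform(30.0, 120.0)
        for crit in criteria:
            # bout of nose pokes, then cue and pellet delivery
            for _ in range(crit):
                if tcur + cue_s + 1.0 > session_s:
                    break
                events.append((tcur, "poke", 0.0))
                tcur += rng.uniform(0.5, 2.0)
            else:
                if tcur + cue_s + 1.0 > session_s:
                    break
                events.append((tcur, "cue", cue_s))
                events.append((tcur + cue_s, "pellet", 0.0))
                tcur += cue_s + rng.uniform(30.0, 120.0)
                continue
            break
        return EventSchedule(events, session_s, variant)

    raise ValueError(f"unknown schedule variant {variant!r}")
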