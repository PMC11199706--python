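# Methods

## The measurement model

The package analyses data from an intensiometric GPCR-based fluorescent
sensor: a receptor scaffold with a circularly permuted GFP whose
brightness increases when the peptide ligand binds. Binding is modeled as
two-state mass action,

    dB/dt = k_on · L(t) · (1 − B) − k_off · B,
    F(t)  = F₀ · (1 + R_max · B(t)),

where B ∈ [0, 1] is fractional occupancy, L(t) the free ligand
concentration (M), and R_max the maximal fractional fluorescence increase.
Two consequences of this model shape everything downstream:

- at equilibrium, B = L/(L + K_d) with K_d = k_off/k_on — a one-site
  (Hill slope 1) saturation curve, so equilibrium titrations are fitted
  with the three-parameter Hill equation;
- after a concentration step, B relaxes mono-exponentially with rate
  k_on·L + k_off, so kinetic experiments are fitted with mono-exponential
  association/decay models.

The propagator in `simulate.simulate_binding_response` advances the exact
per-segment solution of this ODE on the sample grid (the ligand series is
piecewise constant), so simulated traces are analytically exact; the test
suite verifies it against an independent `solve_ivp` integration.

## Simulator defaults and what they emulate

| parameter | default | rationale |
|---|---|---|
| k_on | 1×10⁶ M⁻¹s⁻¹ | typical peptide–receptor association scale |
| k_off | 0.029 s⁻¹ | gives K_d = 29 nM, matching the tens-of-nM apparent affinity of high-affinity peptide sensors, and a ≈1 s⁻¹ relaxation for a 1 µM step |
| R_max | 3.88 | 388% maximal ΔF/F₀ |
| photometry rate | 1017.25 Hz | the acquisition rate of the emulated fiber-photometry system |
| line-scan rate | 800 Hz | the emulated high-speed confocal line-scan rate |
| motion_bandwidth | 2 Hz | locomotion-scale artifact band |
| control_gain | 0.7 | isosbestic channel dimmer than the signal channel |

Bleaching is a multiplicative decay curve (power-like, biexponential, or
polynomial; normalized to 1 at t = 0) shared by both channels. Motion
artifacts are low-pass-filtered Gaussian noise applied multiplicatively
with an identical waveform on both channels before channel gain, which is
exactly the correlated-artifact structure isosbestic correction assumes;
in the noise-free limit the correction is therefore perfect, and the test
suite uses that limit as an oracle. Read noise is additive, independent
per channel.

Event schedules reproduce the emulated paradigms: 15 cued-sucrose trials
(5-s tone then 5-s spout access, inter-trial interval uniform on
45–75 s, 5-min flanking baselines); four 10-s tail lifts (ITI uniform on
120–300 s); fixed-ratio operant sessions; and progressive-ratio sessions
whose poke criteria follow nᵢ = 5e^{i/5} − 5 rounded half away from zero
(that rounding, not banker's or floor, reproduces the canonical sequence
1, 2, 4, 6, 9, 12: 2.459→2 but 8.591→9). The mapping from behavioral
events to ligand at the recording site (sustained rise after an injection,
double-exponential transients for rewards and tail lifts) is simulator
plumbing with amplitudes in units of K_d — a device to make transients
resolvable after the pipelines' smoothing windows, not a claim about
release biology.

What the simulator does **not** emulate: photon shot noise and optical
physics, hemodynamic artifacts, channel-specific (uncorrelated) motion,
receptor desensitization, and ligand diffusion gradients. Passing
recovery tests on this generator therefore demonstrates correctness of
the estimators under the stated model, not robustness to every in vivo
nuisance.

## Imaging quantification

ΔF/F₀ uses the mean over an explicit baseline window; a non-positive
baseline is rejected rather than silently producing nonsense, and values
below −1 (physically impossible; they indicate a wrong baseline) are
clipped with a warning. Membrane ROI selection offers the 65%-of-peak
ΔF/F₀ criterion used for line-scan kinetics (default fraction 0.65) and
Otsu thresholding of the temporal-mean image as the auto-threshold
method; a zero-contrast image yields an empty mask plus a warning rather
than an arbitrary split. Bleach correction fits a five-parameter
biexponential to the pre-application segment only (≥20 samples required)
and removes it by division, re-anchored at the fitted initial value —
division rather than subtraction so that subsequent ΔF/F₀ remains
invariant to overall gain; subtraction is available via `mode=`.
Sequential bath-application ladders are quantified as the difference of
3-minute averages taken at the end of each application window and
immediately before it.

## Kinetics

`fit_mono_exponential` initializes from a log-linear regression on the
deviation from the asymptote and solves by nonlinear least squares with
τ bounded to (0, 10 × trace duration]. The fit is exact (to solver
tolerance) on noise-free members of its model class across τ from 0.1 s
to 100 s, and τ is invariant to affine transforms of the trace — both are
property-tested. Pixelwise line-scan fitting min–max normalizes each
masked pixel (the normalization reference being otherwise unspecified,
min–max makes the fit window explicit and gain-free), fits in association
mode from the bolus-arrival time, and summarizes mean/SD/n over converged
fits only, reporting the failure count.

The onset-latency gate defines the plateau as the mean of the final 10%
of the reference-dye trace (robust to noise, since only "the plateau" is
specified) and the baseline as the mean of samples before the application
marker (the first sample when the marker is t = 0). Experiments whose
dye latency reaches 50 ms or more are flagged failed and must be excluded
from aggregates.

## Dose–response

"Three-parameter" means {R_max, EC50, Hill slope} with the lower
asymptote fixed at zero, consistent with responses expressed as ΔF/F₀
over a ligand-free baseline. The fit is parametrized in log₁₀
concentration for conditioning, initialized at EC50 = geometric mean of
the tested ladder, h = 1, R_max = max response, and is flagged
non-converged when the fitted EC50 lands more than 10× outside the
tested range. Replicates are pooled into a single least-squares problem
by default (`pooled=False` fits per-concentration means instead; the two
agree exactly on balanced noise-free data). Normalization divides by the
fitted R_max (default) or the empirical maximum and provably leaves the
fitted EC50 unchanged.

## Photometry pipelines

All three variants share primitives: ordinary least squares of signal on
control (`fit_lls`), non-overlapping block-mean downsampling (an
anti-aliasing choice; a trailing partial block is dropped), and a
centered moving average with shrink-to-valid edges, windows given in
seconds and converted at the post-downsampling rate.

**arc** bins the raw channels to 1 Hz (by whole seconds, so non-integer
acquisition rates are handled), trims one second at each end
(configurable), and fits the bleaching baseline F₀(t) = a(t+t₀)^(−b) + c
(a, b, t₀ > 0) on the pre-injection window of each channel. Each channel
is first normalized by its baseline median so the nonlinear fit — and
hence the output — is exactly invariant to channel gain. "No decay" is
detected by a pre-fit OLS slope test on the baseline window
(slope ≥ 0 → failure), in which case the baseline-window median is
substituted, matching the pipeline's stated fallback; a failed or
non-positive fitted curve falls back the same way. The output is
ΔF/F₀(signal) − ΔF/F₀(control) at 1 Hz.

**baseline_lls** fits the LLS on the pre-injection baseline only,
subtracts the fitted control from the signal, downsamples by 300, smooths
over a rolling 10-s window, and z-scores against the mean/SD of the
processed baseline segment (z-scoring after smoothing, so the z-units
refer to the smoothed noise floor). **session_lls** divides each channel
by its own fourth-degree polynomial fit (computed in rescaled time for
conditioning), fits the LLS over the whole session, divides the signal by
the fitted control, downsamples by 100 and smooths over 1 s; its output
is a unitless motion-corrected ratio, with z-scoring deferred to the
per-epoch stage. Subtraction vs division in the two variants follows the
respective protocols exactly.

Every `ProcessedTrace` carries an ordered provenance of applied steps;
`replay` re-runs it on the raw recording and reproduces the output
bit-for-bit (property-tested).

One caveat worth stating: because `baseline_lls` z-scores to the
processed baseline's own SD, an artifact-free session is a unit-variance
series — the 95th percentile of |z| sits near the Gaussian 1.96 floor by
construction and cannot be driven lower. The meaningful invariant, which
the suite tests, is that the out-of-baseline distribution matches the
baseline one (no artifact leak above the noise floor), and that LLS
correction removes >99% of injected shared-artifact variance.

## Epoch analysis

Epoch rows are half-open windows [onset − pre, onset + post) on the
processed trace's grid; events whose window exceeds the recording bounds
are excluded and counted, as are zero-variance rows when per-epoch
z-scoring is on (they would otherwise produce infinities). AUC is signed
trapezoidal integration over contiguous bins (default 5 s) whose edges
are snapped to the sample grid and anchored at the event onset, extending
both pre and post; snapping makes bin additivity exact, and a final
partial bin is flagged. AUC can be computed on the trial-averaged trace
or per trial — both orders are available since extraction and averaging
commute in the unscored case. Group statistics beyond mean ± SEM
summaries (rank tests, ANOVA) are out of scope; any stats package
consumes the exported tables.

## Problem sizes

The test suite runs simulations at reduced scale — pipeline sessions of
4–25 minutes at 50–250 Hz, line scans of 50 membrane pixels × 4 s at
800 Hz, 100-plate Monte-Carlo batches for Hill-recovery bias — sizes at
which every estimator is fully exercised while the whole suite stays
fast. The acceptance script uses the same scales. Full-rate
(1017.25 Hz) sessions differ only in sample count, not in code path, and
are covered by a dedicated default-rate test.
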