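# fluokit

Quantification toolkit for genetically encoded fluorescent neuropeptide
sensors — GPCR-based probes whose fluorescence reports ligand binding — and
for the fiber-photometry recordings made with them. It covers the full
desk-side analysis stack for this class of experiment:

- **ΔF/F₀ quantification** of imaging traces: `dff(t) = (F_t − F₀)/F₀` with
  `F₀` the mean over a baseline window, plus membrane-ROI selection
  (Otsu auto-threshold, or the 65%-of-peak ΔF/F₀ criterion) and
  biexponential bleach correction for long bath-application recordings.
- **Dose–response analysis**: three-parameter Hill fits
  `R(c) = R_max·cʰ/(EC50ʰ + cʰ)` with zero lower asymptote, reporting EC50,
  pEC50 = −log₁₀(EC50/M) and the Hill slope.
- **Kinetics**: mono-exponential association/decay fits for τ_on and τ_off,
  pixelwise fitting of high-speed line scans, and the bolus-latency gate
  (reference dye must reach 85% of plateau in under 50 ms) that excludes
  diffusion-limited experiments.
- **Photometry preprocessing**: three isosbestic-correction pipelines —
  per-channel ΔF/F₀ against a power-like bleaching baseline with control
  subtraction (`arc`); baseline-period LLS fit, control subtraction,
  300× downsampling, 10-s smoothing and baseline z-scoring
  (`baseline_lls`); and polynomial detrend, whole-session LLS, control
  division, 100× downsampling and 1-s smoothing (`session_lls`).
- **Epoch analysis**: peri-event window extraction with per-epoch
  z-scoring, trial averaging, signed trapezoidal AUC over 5-s bins, and
  post-injection window summaries.
- **A synthetic-data module** that generates every input with known ground
  truth: a two-state mass-action binding model
  `dB/dt = k_on·L·(1−B) − k_off·B` driving fluorescence
  `F = F₀·(1 + R_max·B)`, layered with bleaching, shared motion artifacts
  and noise; line-scan stacks; dose–response plates; and behavioral event
  schedules (cued sucrose, tail lift, fixed- and progressive-ratio operant
  sessions, with the PR criteria following `nᵢ = 5e^{i/5} − 5` →
  1, 2, 4, 6, 9, 12, …).

The package is a library: import it from Python. The `examples/` directory
holds one short script per capability.

## Worked example

```python
import numpy as np
from fluokit import simulate_dose_response, fit_hill3

plate = simulate_dose_response(r_max=3.88, ec50=28.65e-9, hill=1.0,
                               concentrations=np.logspace(-9, -5, 8),
                               replicates=3, cv=0.05, seed=0)
fit = fit_hill3(plate)
print(f"EC50 {fit.ec50*1e9:.2f} nM, pEC50 {fit.pec50:.2f}, "
      f"R_max {fit.r_max:.2f}")
```

prints

```
EC50 29.24 nM, pEC50 7.53, R_max 3.89
```

The plate was generated around a Hill curve with EC50 = 28.65 nM and a
maximal fractional response of 3.88 (i.e. 388% ΔF/F₀) under 5%
multiplicative replicate noise; the refit recovers the potency within a
few percent, and pEC50 ≈ 7.5 places the sensor in the tens-of-nanomolar
affinity range. `examples/02_kinetics.py` does the same round trip for
τ_on (595 ms, pixelwise line-scan fits) and τ_off (57.1 s, wash-off decay
fit).

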