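# Methods

This note documents the models, numerical choices, and limitations of the
package: what is simulated, how the estimators work, and what the passing
tests do and do not demonstrate about real recordings.

## Signal layer

All channels are uniform 2 kHz series. Filtering is a 4th-order
Butterworth low-pass at 15 Hz applied zero-phase (forward–backward), so
the effective magnitude order is doubled and the phase is exactly zero;
this is appropriate because all analysis is offline and the latency
metrics are defined on commanded-versus-measured trajectories, not on
filtered data. Derivatives use the five-point midpoint stencil
(f[i−2] − 8f[i−1] + 8f[i+1] − f[i+2])/(12h), exact for quartics; the two
samples at each series end fall back to one-sided second-order
differences. Cross-recording synchronization detects the single rising
edge of each sync channel at half its peak-to-peak range and shifts both
recordings so the edges coincide at t = 0.

Zero-phase filtering has one consequence worth knowing: it smears an
acausal precursor ahead of a perturbation onset, so signal values *at*
the onset sample are no longer baseline. Differential signals are
therefore referenced to a pre-onset baseline (the mean over
[onset − 125 ms, onset − 75 ms]) rather than the onset sample itself.
The residual precursor limits a noiseless round trip through the filtered
pipeline to about 0.1% in stiffness; the unfiltered path (available via
`lowpass=False` in the fit helpers) recovers generator ground truth to
machine precision and is what the exactness tests use.

## Force-plate mechanics

Ankle torques and per-plate CoP follow the corner/edge channel algebra in
the README; the per-plate CoP is the normal-force moment over the total
normal load, reported in cm in the plate's axis-centred frame, and marked
invalid wherever the plate carries less than 20 N (configurable). Net CoP
weights the right plate by the right vertical-reaction fraction — exactly
the printed convention, kept even though a load-weighted centroid is the
more common formulation — after mapping both plates into a shared frame
separated by a configured inter-plate distance (default 25 cm between IE
axes). Height *d* is fixed per configuration: its variability has a
negligible effect on stiffness estimates. One sign table (in
`twinplat.units`) fixes directions: +DP = dorsiflexion, +IE = eversion,
+AP = anterior, +ML = subject's right.

## Platform model

Ramp-and-hold perturbations are quintic minimum-jerk profiles
θ(t) = A(10s³ − 15s⁴ + 6s⁵), s = t/T, holding at A afterwards; peak
velocity is 1.875·A/T (45 °/s for the 3°/125 ms protocol ramp). Commands
are validated against the ±15° DP / ±10° IE range of motion and the
100 °/s speed cap — violations raise instead of clipping.

Tracking accuracy of a measured ramp is scored by (1) the phase
difference: the mean measured-minus-ideal crossing-time difference over
26 evenly spaced levels from 0.25° to 2.75° (linear interpolation between
samples), and (2) the steady-state error: mean absolute difference over
0.15–0.25 s. Time zero is the ideal trajectory's 0.01° crossing, applied
to both series, so a pure transport delay appears in the phase metric and
a common delay cancels.

The admittance-rendered environment integrates I·θ̈ + B·θ̇ + K·θ = τ(t)
with fixed-step RK4 on the torque's grid. The controller's virtual
damping and inertia are not protocol quantities; defaults are critical
damping B = 2√(K·I) with I = 0.1 kg·m², chosen so steady states are
reached quickly without overshoot. Because the equilibrium is an exact
fixed point of the RK4 map, the steady-state stiffness estimate
(torque/displacement, averaged over test loads) sits at the numerical
floor for any stable step size. Stiffness validation uses static constant
loads; dynamic loading is not modelled.

## Balance pipeline

TOTEX is computed over the full trial window (transients included) on the
net CoP after 15 Hz channel filtering; invalid samples are skipped
pairwise. The passive protocol renders 10,000 / 500 / 250 Nm/rad on both
plates (3 × 60 s trials each, order randomized by seed); the active
protocol drives both plates sinusoidally over the 0.5/1.0/1.5° ×
0.5/1.0/1.5 Hz grid with a 90° inter-plate phase offset (27 trials).
Human TOTEX magnitudes are subject-dependent, so only ordinal effects
(softer → more sway; larger/faster oscillation → more sway) are asserted
on synthetic subjects.

## Impedance pipeline

Platform dynamics are identified from unloaded ramp trials by ordinary
least squares of torque on [θ, θ̇, θ̈]; `inertia_dominance` is the
variance share of the inertial term among the three model terms, and the
identified parameters feed the τ_platform subtraction in the torque
reconstruction.

The standing trigger gate requires the plate CoP within 0.5 cm of the
nominal point *and* the plate load within ±2 kg·g of half bodyweight,
both held for 0.5 s consecutively (dwell resets on any violation), then
adds a seeded uniform 0–0.5 s delay. Absence of a trigger is a valid
outcome, not an error. Synthetic trials use the commanded onset for
windowing, avoiding threshold-crossing bias; a 0.01° crossing detector
exists for measured data.

Walking trials are screened first by foot placement (closed windows:
−0.5/+2.5 cm AP from the DP axis, ±1.0 cm ML from the IE axis), then by
the 3-SD rule: a trial whose torque or position trajectory strays more
than 3 sample-wise standard deviations from the per-sample mean at any
sample is rejected, in a single pass without re-screening. The rule is
applied separately within the perturbed and catch groups — pooling the
groups would flag every perturbed trial against the catch-dominated mean.

Differential signals span 100 ms from onset. Standing: perturbed trials
are averaged and referenced to the pre-onset baseline (no standing trials
are discarded). Walking: the averaged catch trajectory is subtracted from
each perturbed trial, each differential is y-shifted to zero at onset
(baseline-referenced), and the results are averaged before fitting.
Velocity and acceleration come from the five-point stencil computed on a
4-sample-padded window so every retained sample uses the interior
stencil. The fit is non-negative least squares (`scipy.optimize.nnls`)
of Δτ on [Δθ, Δθ̇, Δθ̈] in radians — "constrained" is interpreted as
K, B, I ≥ 0. %VAF is 1 − var(residual)/var(Δτ), clipped to [0, 100] with
a warning if the model underperforms the mean. Symmetry is
non-dominant K over dominant K.

## Synthetic data generator

The generator defines the study conditions; its defaults are fixed, not
tuning knobs.

* **Subject.** 70 kg, right-dominant; ground-truth impedance triples
  (K Nm/rad, B Nms/rad, I kg·m²): dominant DP (320, 6, 0.012), IE
  (60, 2.5, 0.010); non-dominant DP (260, 5, 0.012), IE (48, 2, 0.010) —
  DP several-fold stiffer than IE and a ~0.8 symmetry ratio, in the range
  ankle studies report. Weight sharing 0.5 with a slow smooth fluctuation
  (SD 0.01).
* **Sway** is a white-noise-driven damped second-order (mean-reverting)
  process per axis per foot: ẍ + 2ζωẋ + ω²x = w, ω = 2π·0.3 Hz, ζ = 0.7,
  stationary SD 0.35 cm AP / 0.25 cm ML (the drive follows from
  var(x) = S₀/(4ζω³)). Unlike a first-order process it has finite path
  velocity, so TOTEX is sampling-rate-stable; defaults put rigid-surface
  TOTEX in the tens of cm per 60 s.
* **Compliance coupling** is open loop: the sway moment (load × CoP
  lever) rotates the admittance-rendered platform and the rotation adds a
  CoP shift through a 100 cm/rad COM-height lever, so softer surfaces
  amplify sway. A closed static loop would be unstable at the compliant
  settings — real standing is stabilized by active control, which is
  deliberately not modelled. Commanded oscillation instead couples
  through a 30 cm/rad plate-tilt lever (a direct pressure shift, not a
  COM excursion).
* **Channel decomposition.** A target (CoP, load, τ_DP, τ_IE) state is
  split into 8 channels by the minimum-norm solution for the corner
  normals and a symmetric shear split of the torque residual through
  lever *d*; the split is deterministic and exactly inverted by the
  forward reconstruction. Targets needing negative corner loads raise.
* **Standing trials** hold quiet standing until the real trigger gate
  fires, then add the ramp; plate channels encode ankle response plus
  platform dynamic torque (ground truth K_p = 0.3, B_p = 0.05,
  I_p = 0.4 — inertia-dominated), which the pipeline must compensate.
* **Walking trials** are stance phases at 100 bpm (step 0.6 s, stance
  60% of the 1.2 s cycle = 0.72 s) with stylized double-peak load,
  heel-strike→toe-off angle progression and a push-off-like torque
  template; per-trial amplitude scaling (SD 2.5%), a slow torque wander
  (1% of peak), placement jitter that intentionally violates the
  acceptance windows in some trials, and perturbation onset at 45 ± 2% of
  stance. Torque responses are built with the pipeline's own derivative
  stencil so noiseless round trips are exact.
* **Noise**: white Gaussian per channel (defaults 0.5 N force, 0.01°
  angle). Where a torque SNR is stated (e.g. 20 dB), the torque-channel
  noise SD is set from the RMS of the perturbation response over the fit
  window and routed through the channel lever arms.

What the generator does **not** emulate: neuromuscular balance control,
reflex and voluntary torque components, time-varying impedance within
stance, gearbox backlash, load-cell crosstalk, and subject-specific gait
shapes. Passing tests therefore demonstrate that the estimators are
correct and robust under the stated measurement model, not that the
human-subject magnitudes are reproduced.

## Problem sizes

Defaults are desk scale by design: 30 standing and 40+40 walking trials
per condition at 2 kHz (trials of ~1.7 s and 0.72 s), 60 s balance
trials; the whole validation sweep runs in well under a minute on one
core. Tests use shortened balance trials (1–15 s) where only bookkeeping
or ordinal effects are asserted.

## Known limitations

* The filtered-pipeline round trip is exact only to ~0.1% (zero-phase
  precursor, see above); noise suppression and exactness trade off.
* The compliance coupling is a minimal open-loop stand-in; quantitative
  TOTEX ratios across stiffness levels depend on it and should not be
  compared to human data.
* %VAF is computed on averaged differentials (averaged-then-fit); per-
  trial fitting would score lower under the same noise.
* The 8-channel decomposition picks one of infinitely many valid splits;
  analyses that depend on individual corner loads (rather than their
  moments) would not transfer to hardware.
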