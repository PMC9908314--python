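# Methods

This note documents the models, conventions and numerical choices behind
`tipm`: what the simulator generates, how the analysis stages are defined,
which parameters matter, and what the synthetic validation does and does not
demonstrate about real data.

## The readout model

A tilt "step" trial is: horizontal baseline → millisecond ramp to a signed
eccentric roll angle → hold (15 s by default) → millisecond ramp back →
post-return recording.  An "impulse" is the same excursion compressed into
<13 ms, probing phasic (angular-acceleration) encoding with no steady-state
component.  Angles are signed relative to the recorded neuron: positive =
ipsilateral (ear-down on the neuron's side).  Ramp durations default to
measured galvanometer kinematics (2.2 / 3.9 / 5.3 ms for 10/20/30° steps;
impulse excursions of 5.0 / 5.6 / 13.0 ms with 0.3 / 0.4 / 2.5 ms at the peak
for 10/15/30°).

Because the indicator is slow, the mean ΔF/F in the first second after the
return approximates the steady-state response at the eccentric angle.  All
scalar responses are means over half-open 1-s windows `[start, start + 1 s)`
on sample timestamps, with window edges taken from the stimulus log, never
from trace features — this makes discretization reproducible at ~2.2
volumes/s, where a window holds 2–3 samples.

## Forward simulation

Each model neuron has:

| parameter | units | default | meaning |
| --- | --- | --- | --- |
| `tonic_gain_ipsi` | ΔF/F per degree | U(0.02, 0.12) | steady-state drive per degree of ipsilateral roll |
| `tonic_gain_contra` | ΔF/F per degree | U(0.0, 0.04) | same, contralateral (small but nonzero) |
| `phasic_gain` | ΔF/F | U(0.05, 0.45) | peak of the transient evoked by each rapid transition |
| `decay_class` / `decay_rate` | — / ΔF/F·s⁻¹ | 50% fast-decay, rate U(0.03, 0.15) | hold dynamics: plateau holds the steady state; fast-decay declines linearly from its peak (floored at 0) |
| `rise_tau_s`, `decay_tau_s` | s | 0.18, 1.8 | indicator kernel time constants (literature-typical GCaMP6s values; not measured in any particular dataset) |
| `noise_sd` | ΔF/F | 0.5 | Gaussian measurement noise per recorded volume, as a fraction of baseline fluorescence |
| `utricle_scale` | — | 1.0 | multiplies the ipsilateral tonic gain only; 0.1–0 emulates loss of the utricular otolith |
| `baseline_F` | a.u. | U(100, 1000) | baseline fluorescence (expression level / imaging conditions) |

The drive is `utricle_scale·g_ipsi·max(angle, 0) + g_contra·max(−angle, 0)`,
shaped by the decay class over the hold, plus a delta at each rapid
transition.  Fluorescence is the drive convolved with a causal double-
exponential kernel normalized to **unit area**, so a sustained drive of level
L settles at ΔF/F = L exactly; phasic deltas carry area `phasic_gain / k_max`
so their rendered transient peaks at `phasic_gain`.  The trace is resampled
at the imaging rate (2.2 volumes/s default) and noise is added independently
per recorded volume.  Gain ranges and trial structure (3 trials per
magnitude, 2 stimulus repeats per trial, magnitudes 10/20/30°, both
directions) follow the experimental design the method was developed with;
`noise_sd = 0.5` was chosen so the trial-to-trial CV of 30° ipsilateral peaks
at the central gain (0.07 ΔF/F/°) comes out ≈ 0.19–0.21, matching the
reported reliability of real recordings.  Repeats are rendered as
independent sweeps sharing the trial's protocol, each contributing one row to
the peak table.

Seeding uses a single master seed fanned out through `SeedSequence` spawn
keys indexed by (cell, protocol, trial, repeat): adding cells or trials never
reshuffles the noise of existing ones, and identical configurations are
bit-identical.

**Implied ground truth.** The 1-s post-return window reads the indicator
during its decay, so the expected measured peak is a deterministic fraction
(≈ 0.8 at the default kernel and sampling) of the steady state `gain ×
magnitude`.  The generator therefore records, per cell and direction, the
*implied slope* — the value the noise-free forward model produces through the
exact same extraction — and recovery is judged against it.  Because peak
extraction and OLS are linear in the additive noise, the slope estimator is
exactly unbiased for the implied slope.

## Analysis conventions

* **Normalization.** `trial_baseline`: F0 = mean F over the last 5 s of the
  trial's baseline (error if the baseline is shorter).  For imaging at
  eccentric angles the light path changes, so `anesthetized_baseline` uses an
  externally supplied F0 per cell from an anesthetized recording at the same
  angle.  F0 ≤ 0 is an error, never silently clamped.
* **Responsiveness.** Paired one-tailed t test (α = 0.05) of per-sweep peaks
  against the same sweeps' first-second baseline means.  Pairing is the
  stricter reading of "same cell" testing; a Welch two-sample variant is
  available.  Cells with < 2 sweeps are flagged untestable.  Identically
  zero differences yield p = 1 rather than NaN.
* **Directionality index.** Undefined (flagged) when `R_ipsi + R_contra ≤
  0`; negative numerators are allowed.  How a non-positive denominator should
  be handled is genuinely open — flagging avoids inventing a convention.
* **Sensitivity slope.** OLS over individual trial peaks (pooled, not
  per-magnitude means) vs magnitude in degrees, intercept free.  The free
  intercept absorbs magnitude-independent components — notably the phasic
  transient evoked by the return step itself — which is why it must not be
  pinned at zero.  0° points are not included.
* **Eccentric dynamics.** Time-to-peak is the argmax of ΔF/F within the hold;
  the decay slope is fit from the peak (not the hold onset) to the hold end,
  matching the peak-then-decay morphology of fast-decay cells; requires a
  hold ≥ 10 s.
* **Shuffle-null change classification.** For each cell and direction, all
  (magnitude, peak) pairs from both ages are pooled; age labels are permuted
  preserving per-age trial counts and the magnitude–peak pairing; slopes are
  refit per pseudo-age and the difference recorded (1,000 shuffles by
  default, seeded).  Cutoffs are the null mean ± 2 SD; under an
  approximately Gaussian null this excludes ≈ 4.6% of truly unchanged cells,
  which the null-calibration tests confirm by Monte Carlo.  Zero-variance
  degenerate inputs collapse the cutoffs to a point without error.  Cells
  with fewer than two magnitudes at either age are reported as excluded with
  a reason, never dropped.
* **Early-Tuned labels.** A cell is early-tuned in a direction if its age-1
  slope exceeds the mean + 2 SD of same-age shuffled slopes, where same-age
  shuffles permute magnitude labels among that age's trials.  This rule is
  defined in the field for the contralateral direction (Early Contra
  Responders); applying the identical rule ipsilaterally is this package's
  interpretation, stated here explicitly.
* **Frame-shift QC.** Normalized cross-correlation at every integer lag up
  to 50% overlap, each lag scored by the Pearson correlation of the
  overlapping pixels (zero-mean, unit-variance per overlap).  The shift is
  the argmax lag with ties broken toward the smallest |lag|; no subpixel
  interpolation (integer-resolution argmax matches the matrix-argmax
  definition; subpixel refinement is a possible extension).  Constant frames
  make the correlation undefined and are flagged invalid; a weak peak
  (r < 0.3) sets a low-confidence flag.  Pixel size must be supplied for
  micron conversion.
* **Geometry.** +x lateral, +y rostral, +z dorsal; ventral cells have
  negative z.  Cell positions are relative to the Mauthner lateral-dendrite
  tip of the cell's own hemisphere.  Mounting roll is
  `degrees(arctan(Δz / x̄))` with the mediolateral reference x̄ defaulting to
  171.8 µm.

## Power of the ± 2 SD shuffle rule

A property worth knowing before interpreting "no change" labels: when a cell
*truly* changes its slope by Δ, the age-label permutation null inherits the
between-age separation — with 6 trials per magnitude the noise-free null SD
is ≈ 0.48·Δ, putting the cutoff at ≈ 0.97·Δ, and with 3 trials per magnitude
the cutoff exceeds Δ itself.  The rule is therefore conservative: uniform
slope changes are flagged only when they are large relative to their own
permutation spread, and detection probability for a doubling of a typical
gain saturates near 20–50% at realistic noise rather than approaching 100%.
The monotonicity of detection probability in the true change, and the exact
calibration under no change, are both verified by Monte Carlo in the test
suite; the saturating power is an intrinsic property of the published rule,
reproduced faithfully here, not an implementation artifact.

## What the synthetic validation does and does not show

The generator emulates trial structure, stimulus kinematics, slow indicator
dynamics, directional tonic tuning, nondirectional phasic transients,
hold-decay heterogeneity, utricle-dependent attenuation, anesthetized
controls, and per-volume Gaussian noise.  It does **not** emulate: photon
(Poisson) noise statistics, motion artifacts or slow drift, ROI segmentation
errors, overlapping neuropil contamination, indicator saturation or
nonlinearity, or correlated (network) trial-to-trial variability.  Passing
tests therefore demonstrate the *correctness of the computations* under a
known forward model — unbiased slope recovery, calibrated nulls, exact shift
recovery — not that real data satisfy the model's assumptions.

Two model limitations worth noting.  The fast-decay hold dynamic uses an
absolute decay rate (ΔF/F·s⁻¹), so strongly attenuated responses (e.g.
utricle-null mode) can floor at zero during the hold, making attenuation
appear stronger than the nominal gain scaling for fast-decay cells; scaling
comparisons are best made on plateau populations.  And phasic transients are
magnitude- and direction-independent deltas — adequate for the observed weak,
nondirectional impulse responses, but not a model of rotation transduction.

## Problem sizes

Monte-Carlo validations use 100–1,000 synthetic cells per check (500 for
slope recovery, 1,000 for null calibration and test size, 150 per condition
for the power grid), with 500–1,000 shuffles per cell; the acceptance script
uses 100–300 cells per quantity.  These sizes put binomial standard errors
well inside the asserted bands while keeping the full suite fast on a single
CPU.
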