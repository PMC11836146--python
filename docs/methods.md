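# Methods

## Pipeline overview

One analysis run proceeds in five stages:

1. **Kinematics conditioning** (`kinio`).  Each impact record carries
   three linear-acceleration channels (g) and three angular-velocity
   channels (rad/s) in a headform-fixed Cartesian frame — X
   posterior→anterior, Y right→left, Z inferior→superior, origin at the
   headform centre of gravity — on a uniform millisecond grid.  Records
   are resampled to the canonical grid of 600 samples covering 30 ms at
   0.05 ms, low-pass filtered, and differentiated to obtain angular
   acceleration.
2. **Kinematic metrics** (`headmetrics`).  PLA, HIC (15 ms window), PAA,
   PAV, BrIC, UBrIC and DAMAGE per impact.
3. **Strain metrics** (`tractstrain`).  Per-element Green–Lagrange
   strain histories from deformation gradients, MPS plus four
   tract-related measures for white-matter elements, time-accumulated
   peaks, and per-simulation 95th-percentile summaries.
4. **Ensemble statistics** (`ensemble_stats`).  Helmet-pair Pearson
   correlations at the curve level (concatenated directional
   angular-velocity curves, 1800 samples) and at the element level
   (strain-peak fields on the metric's eligible element set); top-5 %
   high-strain element sets; fields normalized by the simulation's
   95th-percentile summary; Wilcoxon matched-pairs tests for the impact-
   location effect.
5. **Ranking** (`ranking`).  Helmets ranked per strain metric by the
   location-averaged summary (lower is better), Kendall tau-b over the
   10 metric pairs, and pooled Pearson correlations between the 7
   kinematic and 5 strain metrics (35 tests) and among the strains (10).

## Signal conditioning

The low-pass filter is a phaseless 2-pole Butterworth applied forward
and backward (4 poles total): unit DC gain, zero phase lag, and an
amplitude ratio of 1/2 at the cutoff (each pass contributes its −3 dB
point).  Endpoints are handled by reflective (even) padding of at least
four analogue time constants (≥ 12 samples).  The default cutoff is a
literal 1000 Hz; the conventional channel-class presets (CFC60/180/600/
1000 → 100/300/1000/1650 Hz) are available by name, because "SAE filter
at 1000 Hz" admits both a literal-cutoff and a channel-class reading.
The literal reading is the default.

Angular acceleration is always derived from angular velocity by central
differences (second-order one-sided at the ends, ms→s conversion
applied), never read from file, so its provenance is single-sourced.
By default the velocity is filtered *before* differencing — whether the
original processing filtered first is unknowable from a printed summary,
so the choice is exposed as a flag (`filter_first`, default true);
filtering first strictly reduces spurious acceleration peaks.

## Kinematic metric conventions

- HIC integrates the resultant acceleration trapezoidally and searches
  all sample pairs within the 15 ms window via cumulative sums; the
  optimizer provably equals the exhaustive all-pairs search because both
  use the same quadrature.
- BrIC and UBrIC use per-axis maxima of |ω| (and |α|), which may occur
  at different instants.
- UBrIC is computed with the exponent r = 2 applied *outside* the axis
  sum.  The criterion's source publication instead applies an r-norm per
  axis with an outer 1/r; that form sits behind the `original_form`
  flag.  The w* → 0 limit of a term is 0 (the exponential kills the α*
  contribution), implemented analytically so a zero-velocity axis never
  produces NaN.
- DAMAGE integrates M δ̈ + C δ̇ + K δ = −M α(t) from rest with classical
  Runge–Kutta at the kinematics time step, forcing linearly interpolated
  at half steps.  The sign of the forcing does not affect max ‖δ‖.  The
  default M (identity, kg), K (32 142 / 23 493 / 16 935 N/m diagonal with
  a 1 636.3 N/m x–z coupling) and C = 5.9148·10⁻³ s · K follow the
  criterion's published mass-normalised parameterisation; β = 2.9903.
  Instability (displacement exceeding 10⁶ × the static-deflection
  scale, or non-finite values) raises a numerical error.  M must be
  positive definite.

## Tract-related strain

For each white-matter element with reference fiber unit vector a₀, the
deformed fiber direction â(t) = F a₀/‖F a₀‖ defines an orthonormal frame
{e₁ = â, e₂, e₃}; the Green–Lagrange tensor is expressed in that frame
and decomposed into:

- ε_ton = E′₁₁ (signed normal strain along the fiber),
- ε_tpn = larger eigenvalue of the perpendicular 2×2 block,
- ε_tos = √(E′₁₂² + E′₁₃²),
- ε_tps = half the eigenvalue spread of the perpendicular block.

All four are invariant to the arbitrary in-plane choice of e₂, e₃ and to
rigid rotations applied consistently to F and a₀ (asserted to 1e-12 in
the tests).  Conventions:

- **Real-time fiber.**  The deformed direction â(t) is used, not a₀;
  the `reference_fiber` flag switches for sensitivity checks.  The two
  conventions disagree measurably (e.g. 0.130 vs 0.110 for a 1.2×
  uniaxial stretch at 45° to the fiber), so the choice is testable.
- **Tensor shear.**  Shear outputs are tensor components (half the
  engineering shear); `engineering_shear` doubles them.
- **MTON clamp.**  The along-fiber peak is the positive part of the
  signed maximum — axonal-injury reasoning concerns tensile stretch, and
  the clamp keeps MTON ≤ MPS meaningful element-wise.
- The perpendicular basis is built deterministically (e₂ ∝ â × c with c
  the canonical axis least aligned with â) for reproducibility; the
  invariance makes the choice immaterial.

Elements whose deformation gradient loses positivity (det F ≤ 0 at any
time) are flagged invalid, excluded from all summaries, and counted in
the run log.  Percentile summaries use the linear-interpolation
order-statistic convention (NumPy's "linear"); MPS is summarized over
all valid brain elements, tract metrics over valid white matter.

## Ensemble statistics

Curve similarity concatenates the three directional angular-velocity
curves into one 1800-sample vector per record — this, not per-axis
averaging, gives the stated correlation sample size.  Correlation
strength is banded weak (< 0.3), moderate (0.3–0.7), strong (≥ 0.7).
A full 17-helmet ensemble yields C(17,2) = 136 pairs per location, 408
curve-level correlations over three locations, and 2040 element-level
correlations over five strain metrics.

Wilcoxon matched-pairs signed-rank tests discard zero differences
(reporting p = 1 when all differences vanish), use the exact null for
n ≤ 25 and the normal approximation above (or when ties make the exact
method unavailable); significance is p < 0.05.  Top-fraction element
sets take the ⌈f·n⌉ largest peaks with ties broken deterministically by
element id.  Kendall's tau is the tie-corrected tau-b, since average-
rank ties are possible.  Cross-metric correlations pool all 51 (helmet,
location) observations into a single sample per metric pair.

## Synthetic ensemble

The generator emulates 6 m/s oblique drop tests of 17 helmets at three
impact locations onto a 45° anvil, and the FE-like brain output those
kinematics would drive.  Its defaults are the study conditions:

- **Angular velocity.**  Each axis is a single-lobe pulse
  (t/τ)·e^(1−t/τ) with τ ≈ 5–6 ms; the location's dominant axis
  (XRot→x, YRot→y, ZRot→z) carries ≥ 3× the off-axis peak.  Base
  dominant peaks (27, 33, 41 rad/s for X/Y/Z) plant the severity
  ordering ZRot > YRot > XRot; per-helmet lognormal severity
  (σ = 0.10) and 4 % per-record jitter individualise helmets.  Two
  XRot records are pinned to reported directional peaks: helmet P
  (24.4, 6.9, 4.7 rad/s — the typical dominant-x pattern) and helmet Q
  (11.7, 12.7, 9.6 rad/s — the multi-axis outlier).  The outlier uses a
  damped-sine waveform with per-axis periods, which is what decorrelates
  its concatenated curves from the single-lobe records.
- **Linear acceleration.**  A shared-direction pulse scaled to a peak
  resultant of ~120–130 g per location, clipped to a 75–180 g band.
- **Strain fields.**  An abstract element lattice (default 5000
  elements; 40 % white matter, of which 5 % corpus callosum and 5 %
  cerebellar WM by contiguous blocks) with fixed per-element symmetric
  direction matrices of unit spectral radius and regionally coherent
  fibers.  Per location, a standardized sum of Gaussian-smoothed spatial
  modes S(e) is shared by all helmets; per impact,
  F_e(t) = I + a_e·p(t)·D_e with amplitude
  a_e = gain · PAV · |S(e) + noise|, gain 0.004 per rad/s and element
  noise at 0.15 of the field SD.  The outlier impact draws an
  independent mode field.  Amplitudes are clipped at 0.55 (logged) so
  det F stays positive.  Strain histories use 61 samples over 30 ms —
  a typical FE output interval of 0.5 ms, coarser than the kinematics.

Routing strain severity through the record's PAV is what makes angular
kinematic metrics correlate strongly with strain summaries downstream;
the shared-versus-independent mode structure is what separates
non-outlier (r > 0.7) from outlier (r < 0.7) element-wise correlations.
Everything is deterministic under the seed: every draw comes from a
stream keyed by (seed, stage, helmet, location), so ensembles are
bitwise reproducible and structural contracts survive seed changes.

What the generator does **not** emulate: brain geometry and anatomy
(the lattice has no biofidelity), contact/impact physics, helmet
material behaviour, strain-rate effects, and the heavy-tailed element
populations of real FE meshes.  Passing tests therefore demonstrate the
*analysis machinery* — metric definitions, enumeration, statistics, and
recovery of planted structure — not predictions about real helmets.

## Problem sizes

The test suite and the acceptance script run the full 17 × 3 ensemble
over a 2000-element mesh (800 white-matter elements), which preserves
every enumeration count and leaves comfortable statistical margins on
the correlation bands; the generator's 5000-element default is used by
the CLI.  Brute-force cross-checks use 50 random records for HIC, 100
random (F, a₀) pairs against a 10⁴-direction sampling oracle for the
perpendicular strains, and characteristic-polynomial roots for MPS.

## Limitations

- Absolute metric magnitudes (e.g. HIC) depend on synthetic pulse
  shapes and are only plausibility-scaled, not calibrated to any
  laboratory dataset.
- Helmet rankings computed on synthetic data reflect the planted
  severity structure, not real helmet performance.
- The DAMAGE default matrices are transcribed constants; analyses that
  depend on them should verify against the criterion's source.  All
  closed-form checks in the tests use synthetic single-axis
  configurations instead.
- Tract measures assume a single fiber direction per element; crossing
  fibers are not represented.
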