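# Methods

This note documents the analysis model, the numerical choices made where
the procedure was genuinely open, the synthetic-data generator's scope, and
known limitations. It states nothing the test suite or
`scripts/acceptance.py` does not itself compute.

## Signal model and assumptions

The input is a uniformly sampled single-axis angular-velocity record
ωx(t) (rad/s) of the upper back during ergometer rowing, nominal step
dt = 1 ms. The analysis assumes:

* the rowing motion is cyclic with stroke period T ≈ 2–4 s, and the shape
  of one cycle is dominated by the fundamental and the second and third
  harmonics;
* the drive (rower loaded, body tilting forward→backward against the
  ergometer) has ωx < 0 and the recovery has ωx > 0, so the sign of ωx
  identifies the phase and negative→positive zero crossings delimit
  strokes;
* measurement noise lives above the stroke band and can be removed by a
  low-pass at 2.23 Hz without touching the harmonics that carry the curve
  shape (for T ≥ 1.794 s at least the fundamental plus four harmonics are
  retained, since harmonic m survives iff m/T ≤ f_cutoff).

## Smoothing

Brick-wall low-pass in the discrete Fourier domain: components with
f > f_cutoff are zeroed (the bin at exactly f_cutoff is kept, matching the
"remove what exceeds the cut-off" reading), and the signal is reconstructed
by the inverse real FFT. The full record is transformed as-is — no
zero-padding, tapering or detrending. Records are minutes long, so spectral
leakage at the 2.23 Hz boundary negligibly affects the retained band; the
filter is exactly idempotent and linear, which the tests assert at 1e-12 /
1e-9.

`f_cutoff` default 2.23 Hz (period 0.448 s ≈ 0.45 s), configurable via
`smoothing.f_cutoff_hz` or `--f-cutoff`; values at or above Nyquist are
rejected.

## Segmentation

A crossing is a pair of successive samples v_i < 0 < v_{i+1}; its time is
found by linear interpolation, removing the ±1 ms quantization bias of
snapping to samples (durations are reported to 0.01 s). Samples exactly
zero terminate the preceding sign run: a zero between a negative and a
positive sample yields one crossing at the zero's time; a run of zeros
yields one crossing at the run midpoint.

One stroke spans two consecutive upward crossings; incomplete data before
the first and after the last crossing are discarded. Because boundaries are
upward crossings, the recovery sub-interval precedes the drive
chronologically inside a segmented stroke; the phase *labels* follow the
sign convention (phase 1 = drive = negative), not time order. Phase
durations are the total measure of {ωx < 0} and {ωx > 0} within the stroke
for the piecewise-linear interpolant, summed over all sign runs — so
micro-ripples after smoothing cannot break T = T₁ + T₂, which holds to
1e-9 s by construction (a degenerate all-zero plateau, impossible for
generic float data, would be split evenly between the phases to preserve
the identity). Strokes shorter than 0.45 s (the cut-off period) are flagged
in the log but retained: no silent stroke rejection is applied anywhere.

## Duration statistics

Per-trial summaries are arithmetic means and sample SDs (n − 1 denominator;
SDs undefined, not zero, for a single stroke). Group summaries are the mean
and SD over the participants' per-trial means, so group n is the number of
participants — consistent with the longitudinal tests, which operate on
participant-level values. Pooling all strokes of all participants was
rejected because it would weight participants by stroke count and mismatch
the tests' sampling unit. Group phase means therefore need not sum exactly
to the group full-stroke mean when trials differ in usable strokes; only
the per-stroke identity is exact.

## Mean stroke profile

"Aligned" strokes are realized as fixed-length windows of
round(⟨T⟩/dt) + 1 samples anchored at each stroke onset (values at the
fractional onset grid obtained by linear interpolation); windows that would
overrun the record are dropped, and at least two must remain. Alternatives
— truncation to the shortest stroke, or time-normalized resampling — were
rejected because the instability integral runs over the absolute time axis
[0, ⟨T⟩], and every grid point should average the same number of strokes.
The profile is the point-wise mean and sample SD across windows.

Under pure period jitter the SD curve peaks near the zeros of the mean
curve (phase-transition timing scatter), which the tests check on
simulated ensembles.

## Instability index

value = 100% × (1/⟨T⟩) ∫ STD(ωx)(t) / |⟨ωx⟩(t)| dt, trapezoidal rule.

Numerical choices:

* **Excluded points.** The integrand is singular where the mean curve
  vanishes. Excluded are the two grid endpoints (zeros by the crossing
  convention) and, for each interior sign change, the two bracketing
  samples — for the generic single interior zero this is the classic
  "three excluded points" (two boundary + one interior) pattern, stated
  per exclusion *site*. Excluding the bracketing pair rather than one
  nearest sample keeps the integrand finite for any float data; the
  single-sample variant is available as `exclusion="nearest"` and agrees
  within 1% on dense grids. Profiles with ripple-induced extra zeros warn
  but remain computable.
* **Piecewise quadrature.** Each excluded point splits the domain; the
  trapezoidal rule is applied over each remaining contiguous run, i.e. the
  sub-intervals adjacent to an excluded sample contribute nothing.
* **Normalization** is by the full ⟨T⟩ as the formula is written, not by
  the retained measure; on a 1 ms grid the difference is ~0.2%.
* **Absolute value.** The denominator uses |⟨ωx⟩(t)|, making the index
  non-negative and scale-invariant (both curves scale together).
* **No regularization.** |⟨ωx⟩| is not floored: large values (> 100%) near
  the phase transition are the signal — they quantify delayed/advanced
  individual phase transitions — and must not be suppressed.

The analytic two-window ensemble (1 ± ε)·s(t) has integrand ε√2 wherever
s ≠ 0, so the index converges to slightly below 100·ε√2 % (14.14% at
ε = 0.1); the implementation matches this and an independent 10×-resolution
Riemann oracle within 2%.

## Exact rank tests

With 7 participants per stage, normal approximations can flip borderline
calls, so both tests use exact permutation nulls:

* **Rank-sum:** all C(n₁+n₂, n₁) assignments of the combined mid-ranks.
* **Signed-rank:** all 2^m sign patterns on the m non-zero differences;
  zero differences are dropped before ranking (the Pratt alternative
  changes p at n = 7 and was not adopted); all-zero differences give
  p = 1 with a warning.

Mid-ranks are multiples of ½, so doubling them gives integer weights and
both null distributions are built by an exact integer dynamic program —
ties therefore cost nothing and counts stay exact in 64-bit integers up to
the supported sizes (combined n ≤ 40 / m ≤ 30). Two-sided p = 2·min(tails),
capped at 1; swapping samples or applying any strictly increasing transform
leaves p unchanged. The tests verify agreement with brute-force enumeration
(all instances random, n ≤ 8, ties forced half the time) and with scipy's
exact methods in tie-free cases, and calibrate the null rejection rate at
≤ nominal over 10,000 replicates.

The significance matrix tests, per stage pair and grade, the participants'
mean durations and their duration SDs for full stroke / phase 1 / phase 2
with both tests; stage pairs are the consecutive ones plus first↔last.
Headline counts use the two sequential pairs × grades × the two phases.
No multiple-testing correction is applied, mirroring the longitudinal
design this implements; the run log and `TestMatrix` metadata say so.

## Synthetic-data generator

What it emulates: an asymmetric three-harmonic stroke waveform (fixed
template constants A = (1, 0.45, 0.15), φ = (0, 5π/4, 7π/8), chosen once by
root-finding so the negative drive lobe occupies 63.6% of the period — the
2.1 s / 1.2 s split of a 3.3 s stroke — with exactly one upward crossing
per period), stroke-to-stroke period jitter (default SD 0.08 s) applied by
rescaling whole cycles in time so the waveform stays continuous at the
zero-valued boundaries, amplitude jitter (default 5%), and Gaussian noise
synthesized in the frequency domain confined to 3–40 Hz (default SD
0.15 rad/s) so the smoothing stage removes it almost exactly. Records carry
a quarter-period lead-in and tail from virtual neighbouring cycles, tapered
to zero at the record ends so the periodic spectrum has no wrap
discontinuity and the brick-wall filter does not ring at the edges; every
generated stroke is then bounded by detectable crossings and the ground
truth lists each true period and phase split exactly.

Cohorts add per-participant baseline offsets for both phase durations
(between-subject SD 0.05 s each) and per-stage / per-grade additive phase
shifts, realized by piecewise-linearly warping the template's recovery
fraction — so "phase redistribution at constant full period" scenarios have
exact ground truth.

What it does **not** emulate: harmonic-shape differences between athletes,
fatigue drift within a bout, sensor mounting artefacts, slow baseline
wander below the stroke band, or non-Gaussian noise. Passing recovery
tests on this generator therefore demonstrates correctness of the pipeline
arithmetic under the stated signal model, not robustness to every artefact
of real recordings.

## Problem sizes

Tests and the acceptance script run entirely on synthetic data at desk
scale: single trials of 6–200 strokes at 1 kHz; the phase-additivity sweep
over 10,000 strokes; 10,000 (suite) / 5,000 (script) null replicates for
test calibration; 50-seed cohort batches of 7 participants × 2 stages ×
20 strokes for the significance-signature rate; and one 7 × 3 × 3 cohort
of 40-stroke trials for the end-to-end study emulation.

## Limitations

* Only the x-axis gyroscope channel is analysed; multi-axis fusion and
  angle reconstruction are out of scope.
* The zero-crossing criterion presumes the smoothed signal changes sign
  once per stroke; pathological waveforms (e.g. double-peaked drives
  surviving the low-pass) would over-segment, though the phase-measure
  construction still keeps durations consistent.
* Exact tests are limited to the small samples they are meant for
  (combined n ≤ 40); larger cohorts would need the normal approximation,
  deliberately not provided here.
* The instability index depends on dt through the excluded measure around
  mean-curve zeros; at 1 ms steps and ~3 s strokes this is a ~0.2% effect
  (the grid-refinement test bounds it at < 1%).
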