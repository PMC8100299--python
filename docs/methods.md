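# Methods

## Signal model and what the simulator emulates

A frame is a real amplitude vector over range (delay) bins sampled at a
fixed frame rate.  The simulator composes each frame from a static
clutter profile (smooth low-pass-filtered noise per sensor), one moving
target path per sensor (a Gaussian-modulated-cosine pulse template at a
base delay), and i.i.d. Gaussian receiver noise per bin and frame.
Movement is encoded kinematically, not electromagnetically: a latent
per-frame movement-intensity series drives the standard deviation of
independent per-frame jitter of the target's delay bin
(`delay_jitter_per_intensity`, default 1.5 bins per unit intensity) and
of its relative amplitude (`amp_jitter_per_intensity`, default 0.2 per
unit intensity).  Larger intensity therefore means larger
consecutive-frame envelope changes, which is precisely the quantity the
scoring chain thresholds and counts.

The pulse template is a zero-mean, peak-normalized Gaussian-modulated
cosine in bin units (default half-width 3 bins, carrier 0.2 cycles/bin,
support ±3 envelope SDs).  The real device's RF specifics (GHz carrier,
oversampling, bandwidth) are deliberately not modelled: the activity
score depends only on frame-to-frame changes of the demodulated
envelope, so any band-limited oscillatory template with a realistic
shape exercises the same code paths.  There is no propagation physics,
no antenna pattern, no radar cross-section model, and no multi-person
scene; passing tests demonstrate that the *algorithmic chain* behaves
correctly on signals with the assumed structure, not that the chain is
robust to every artefact of real hardware.

### Latent trajectory model (group profiles)

Mean intensity is piecewise linear in time *t* (minutes):
`m(t) = baseline` for `t < changepoint`, and
`baseline + trend·(t − changepoint)` afterwards.  Noise is
`scale(t)·(b + w(t))` where `b ~ N(0, between_subject_sd²)` is a
per-subject offset, `w(t)` interpolates independent per-minute Gaussian
knots with SD `within_noise_sd` (so the dispersion survives per-minute
averaging instead of being washed out by 1200-frame means), and
`scale(t)` equals `dispersion_scale` after the changepoint and 1 before.
Intensities are clipped at zero.

Study-condition defaults, fixed once: HC baseline 1.0, trend 0,
dispersion 1.0; ADHD baseline 1.0, trend 0.06 min⁻¹ after the
changepoint at minute 7, dispersion 2.0; `between_subject_sd` 0.25,
`within_noise_sd` 0.15; sessions 22 minutes, 4 sensors, 20 frames/s,
cohort 10 ADHD vs 15 HC.  The trend and dispersion values were chosen so
that the ADHD mean rises visibly but modestly relative to within-group
spread over the session (roughly doubling the HC mean by minute 22 with
clearly inflated post-changepoint dispersion), a qualitative shape
matching slow-rising, high-dispersion hyperactivity profiles; they are
ordinary config fields, not magic numbers.

One integer seed determines everything: the cohort seed spawns one
`SeedSequence` child per subject plus one for the empty room; each
subject child spawns trajectory, scene and render streams; the render
stream spawns one stream per sensor.

## Scoring chain

* **Clutter removal**: `C_n = α·C_{n−1} + (1−α)·x_n`, `y_n = x_n − C_n`,
  applied in that order.  α defaults to 0.97 (unitless forgetting
  factor): slow adaptation so sustained motion is not absorbed into the
  clutter estimate.  α = 0 makes the update degenerate (`y ≡ 0`), so the
  pipeline requires α ∈ (0, 1]; the single-step API accepts the full
  [0, 1] range and documents the degeneracy.  The stream implementation
  evaluates the recursion as a first-order IIR filter
  (`scipy.signal.lfilter`) and is tested against the literal per-frame
  loop.  The initial clutter estimate is the first frame.
* **Envelope**: magnitude of the analytic signal along range bins
  (`scipy.signal.hilbert`), verified against an explicit DFT
  construction (zero negative frequencies, double positive ones).
* **Threshold calibration**: per sensor, `T = mean + m·SD` (sample SD)
  of `|A_n[k] − A_{n−1}[k]|` pooled over all bins and all post-burn-in
  frames of an empty-room recording.  Multiplier m defaults to 3.0
  (three-sigma false-alarm control under roughly Gaussian envelope
  noise); burn-in defaults to 100 frames (5 s at 20 fps) to let the
  clutter recursion converge, and shrinks automatically for very short
  calibration recordings.  A noise-free empty room yields T = 0, which
  is degenerate: the detection rule is inclusive (`≥ T`), so T = 0 marks
  every bin as moving.  Calibration recordings should contain receiver
  noise, as real ones always do.
* **Counting**: `Q_i[n]` counts bins whose envelope changed by at least
  `T_i`.  The first frame has no predecessor and is assigned
  `Q_i[0] = 0`, so per-frame series have exactly `n_frames` values — a
  20 fps recording produces exactly 20 values per second and a
  22-minute session exactly 22 one-minute blocks.
* **Fusion**: the across-sensor median (even counts: midpoint of the
  middle pair), permutation-invariant and robust to one sensor being
  masked by the subject's body.  Fused values may be half-integers.
* **Aggregation**: arithmetic mean of `QAR[n]` within non-overlapping
  60-s blocks; a trailing partial block is kept if it covers ≥ 30 s.  A
  `median` mode is available as a config switch for the alternative
  reading in which the per-minute summary is a median; the default is
  the mean.  The total is the sum of minute scores.

## Functional ANOVA

Curves are interpolating cubic splines (not-a-knot ends, no penalty)
through the minute scores at knots t = 1..D, evaluated on a 221-point
uniform dense grid spanning the knot range [1, D] — extrapolating below
the first knot is undefined, so the grid and all integrals use the knot
span.  At each grid point the classical one-way ANOVA F statistic is
computed (df 1 and N−2 for two groups).  The GPF statistic is the
trapezoid-rule average of F(t) over the domain; the F-max statistic is
its grid maximum.

Both null distributions come from permuting group labels over whole
curves (B = 1,000 by default, configurable), with the add-one estimate
`p = (1 + #{stat* ≥ stat}) / (B + 1)`, which is never zero and exact in
expectation at any sample size.  The resampling route was chosen over
the asymptotic χ²-mixture approximations from the functional-ANOVA
literature because the target sample sizes (10 vs 15) are small and the
permutation test requires no distributional assumptions; an asymptotic
mode is out of scope.  Both statistics are computed from one shared set
of permutations (`mean_function_tests`), which keeps them consistent
and halves the cost; the permutation F is fully vectorized across
permutations and grid points via group-sum algebra.

Grid points with zero within-group variance but distinct means are
flagged +inf, logged, and excluded from the GPF integral (and from the
F-max maximum).  Velocity curves are the analytic spline derivatives
(score/minute) on the same grid; the same tests apply unchanged.  No
multiple-testing correction is applied across the five
distribution-summary time points (3, 7, 9, 11, 22 min).

Scalar comparisons: Wilcoxon rank sum, computed by exhaustive
enumeration of all group assignments with midranks when the pooled
sample size is ≤ 12 (exact even under ties) and by the tie-corrected
normal approximation otherwise; Pearson chi-square (no continuity
correction) for categorical tables; Spearman's rank correlation with
midrank ties for associations.

## Numerical choices and degenerate inputs

* Tolerances: envelope vs DFT oracle < 1e−8; pointwise F vs
  sums-of-squares oracle < 1e−10; exact enumeration p-values to 1e−12.
* Even-count medians use the standard midpoint convention everywhere.
* Recordings shorter than one minute cannot be aggregated (error);
  calibration needs ≥ 2 frames; curves need ≥ 2 subjects per group and
  ≥ 2 knots (velocity: ≥ 2 grid points).
* Target delays that jitter outside the range window are clipped to the
  window edge with a logged warning.
* Containers store little-endian float32 row-major matrices plus a JSON
  sidecar; byte counts are validated against the sidecar on read, so
  truncation or shape edits are detected before any computation.

## Problem sizes used by the test suite and acceptance script

Simulated recordings use 64 range bins (the bin count is free in the
model; 64 keeps full 22-minute, 4-sensor cohorts cheap while leaving
the chain unchanged).  Calibration experiments use 1,000 null trials
and 500 power trials with B = 199 permutations at n = 10 vs 15;
end-to-end correlation checks use 20 independent 10-minute ramp
recordings.  The whole suite and the acceptance script each complete in
about a minute on one CPU.

## Known limitations

* Movement intensity is a scalar; posture, direction and position are
  not modelled, and the simulator cannot produce sensor-specific
  occlusion patterns beyond random path geometry.
* Absolute score scales depend on the bin count and jitter coupling
  constants, so totals are comparable within a configuration only.
* The permutation tests assume exchangeability of whole curves under
  H0; heteroscedastic group differences with equal means can inflate
  rejection beyond the nominal level, as for any label-permutation
  test.
* Real-device concerns — drift, interference, retro-reflective clutter
  changes (doors, curtains), multiple people — are out of scope.
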