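# Methods

This note records the analysis model, the synthetic-data model, and the
numerical choices that were genuinely open, in enough detail to
reproduce or audit any number the package emits.

## Drawing-task analysis

**Preprocessing.** Raw pen records (nominally 200 Hz; time s, position
mm, pressure arbitrary units) are smoothed with least-squares cubic
regression splines with interior knots every 6 samples.  Knot density is
the only smoothing control — there is no roughness penalty — so the fit
is a plain linear least-squares problem and the derivative channels come
from the spline analytically (a finite-difference fallback on the
smoothed samples is available and agrees to ~0.1%; analytic is the
default because it avoids a second discretisation).

**Segmentation.** Movement onset is the last sample before the first
significant speed peak at which the tangential speed is below 5% of the
trial's global peak *and* pen pressure is positive; offset is the last
sample above the same 5% threshold.  "Significant" is operationalised
as peak prominence ≥ 5% of the global maximum (`peak_prominence_fraction`,
configurable) — some such ripple criterion is unavoidable and any peak
count on noisy data inherits it.  If the pen touches down only after the
speed threshold is already exceeded, onset falls back to the first
pen-down sample before the peak.  Endpoint samples carry one-sided
derivative stencils and are never used as extrema.

**Extrema and substitution.** Speed peaks come from a prominence-
filtered peak search; each trough is the minimum between two consecutive
retained peaks, which guarantees strict peak/trough alternation.  When
only 3 (or 2) peaks survive because consecutive strokes merged, the
vanished peak–trough pair is restored from the inflection point (zero
crossing of the second time-derivative of the speed) that replaced it:
one height for both the missing peak and the missing trough.  Locating
the merge: detected troughs are matched to the expected via-point
passage times — fractions (0.25, 0.5, 0.75) of the segment, matching the
roughly equal stroke durations of the task — by order-preserving
minimum-cost assignment; each unmatched fraction marks a merged region,
searched between the flanking detected extrema, taking the inflection
nearest the expected time (first by time on ties).  The substituted pair
is inserted at the inflection time, the peak offset by half a sample to
preserve strict alternation.

**Scoring.** score = 100·mean(t₁,t₃)/mean(p₁..p₄), troughs indexed
temporally; the middle trough (the far target, where even skilled movers
stop) is excluded by the formula.  For any profile whose troughs lie
below their adjacent peaks the score is bounded in [0, 100].  Baseline
normalisation subtracts the subject's pre-test mean and deliberately
does **not** divide by it (pre-test scores cluster near zero).  The
pre-test *mean* (not median) is the baseline; configurable.

**Spatial error.** Targets are disks (default radius 2.5 mm — the
printed dot size is a layout parameter, not a given).  Per target the
closest approach of the segment's samples to the disk edge is taken,
clamped at zero inside the disk, and the four values are summed.
Distances are sample-to-centre without inter-sample interpolation: at
200 Hz and ordinary pen speeds the sample spacing is a fraction of a
millimetre, far below the disk radius.

**Duration and improvement.** Duration is offset − onset.  Duration
improvement is 100·(baseline − value)/baseline, positive = faster; the
raw signed change is also emitted.  Per-subject phase summaries report
means for scores and both medians and means for error and duration
(error and duration are zero-inflated / skewed).

## Tracking-task analysis

**Preprocessing.** Only the horizontal axis is analysed (the task
physically constrains vertical motion).  The recipe is: two-way
(forward–backward) 4th-order Butterworth low-pass at 5 Hz → finite
differences at the native rate → linear resampling of all channels to a
uniform 100 Hz grid.  Two-way application makes the net phase shift zero
(peak timings preserved within one sample) and squares the magnitude
response (>99.9% attenuation at 20 Hz).  The analysis-side stimulus is
regenerated from its program and interpolated onto the follower's grid,
so file-precision timestamp round-off cannot misalign the pair.

**Jitter.** Acceleration zero-crossings are located by sign change with
linear sub-sample interpolation; runs of exact zeros count only when the
sign flips across the run.  Crossings within `stim_match_window` (50 ms
default — the obligatory-crossing tolerance is not a given; 50 ms is
half the refractory window) of any stimulus acceleration zero-crossing
are removed, then events closer than 200 ms to the previously retained
event are dropped (earlier event kept): voluntary corrections are not
produced faster than 5 Hz.  Jitter frequency per consecutive pair is
1/(2·Δt), bounded below 2.5 Hz by the refractory rule.  The summary
statistic is the argmax of a Gaussian KDE over the pooled jitter
frequencies (Silverman bandwidth by default, recorded in every summary;
an absolute bandwidth in Hz may be supplied).  Trials rarely yield
enough events on their own — the pipeline pools events per subject,
phase and stimulus-frequency block (each event pair is assigned to the
block containing its midpoint) and requires ≥ 5 values per pool.

**Tracking errors.** dX and dV as printed in the README, evaluated on
the common grid.  Both denominators are guarded: samples with
|v₁+v₂| < 1 mm/s (dV) or |x₁+x₂−2x_c| < 1 mm (dX) are excluded from the
sum and from n, with the exclusion count logged — both expressions are
singular when follower and stimulus meet at zero velocity / at the
centre, and the low-frequency stimulus passes through both regularly.
dT matches stimulus zero-velocity events to follower zero-velocity
events one-to-one, greedily by smallest absolute time difference
(stimulus-anchored); surplus events on either side are ignored.  The dV
numerator uses |v₁−v₂| throughout.

## Synthetic-data model

**Drawing trials.** Four minimum-jerk strokes (quintic profile, zero
endpoint velocity/acceleration, peak speed 15/8·distance/duration at
midstroke) between the four layout targets.  Consecutive strokes are
composed either with dwells (full stops: speed exactly zero at the
via-point) or with temporal overlap: the next stroke's onset is advanced
by overlap × its duration and the velocity profiles are summed — the
standard superposition construction for blended movement sequences.
Overlap and dwell are per-via-point (B, C, D) and mutually exclusive at
each.  Pressure is 0 during a 0.3 s lead-in resting at A and 1.0 from
movement start, so the pressure-gated onset rule is exercised.  Gaussian
position noise (`noise_sd`) is available but defaults to 0: clean trials
make ground truth exact, and every noise-robustness statement is tested
explicitly at a stated noise level instead of implicitly everywhere.
The ground-truth sidecar stores the stroke schedule and the analytic 5%
threshold-crossing bounds of the clean composed profile (computed on a
10× finer grid), which is what a correct detector should recover.

Limitations worth knowing: velocity superposition bends the path inside
the via-point corner, so high-overlap trials *cut* the corner and incur
genuine spatial error — real skilled movers curve *through* the targets.
Consequently overlap values ≳0.6 also change the peak topology (merges),
and the score-vs-overlap relation is monotone only below that; the
monotonicity check uses overlaps 0–0.5.  Default stroke durations 0.5 s
(trial ≈ 3 s with lead-in/out) and a centred 100 mm square layout are
plausible for the task but not canonical.

**Stimulus.** Half-sine *velocity* waves: within a half-wave of
frequency f the speed is a half-sine over 1/(2f) seconds and the
direction alternates, so the pen shuttles between x_c and
x_c + amplitude with position and velocity continuous everywhere —
including across frequency-block boundaries, where velocity is exactly
zero.  Acceleration zero-crossings fall only at the half-wave midpoints
(velocity extrema).  Default amplitude 100 mm (a comfortable excursion
on a tablet-sized track); block frequencies are configuration — 0.25 and
0.375 Hz are protocol values, the rest of the default set
{0.5, 0.75, 1.0} are placeholders.  Real stimuli in such experiments are
recordings of a human leader; this idealisation has a cleaner
acceleration-crossing structure than a human's.

**Follower.** Base = stimulus delayed by `follower_delay` (initial
position held).  Corrections:

* *Programmed whole-wave frequency f* — an oscillatory over/under-
  correction: a sinusoid at f superposed on the base, with a seeded
  random phase and amplitude max(`correction_amplitude`, 3·â/ω²) where â
  is the stimulus's peak acceleration.  The 3× margin guarantees the
  follower's acceleration crosses zero at every wobble half-period
  (displaced by at most arcsin(1/3)/ω where stimulus acceleration
  peaks), so retained events are spaced 1/(2f) and the half-reciprocal
  rule recovers f exactly.  The random phase prevents systematic
  phase-locking to commensurate stimulus blocks, which would eliminate
  events wholesale via the obligatory-crossing exclusion.  In slow
  tracking the implied corrective velocity is comparable to the stimulus
  velocity, which matches the qualitative appearance of real follower
  velocity traces.  An isolated-bump construction was evaluated and
  rejected: brief position bumps generate acceleration crossings on both
  flanks wherever the stimulus acceleration opposes them, and the 5 Hz
  two-way filter rings on sub-0.2 s bumps, so the recovered frequency is
  biased upward by up to ~0.25 Hz — the bump model does not implement
  the frequency it advertises.
* *Poisson rate* — isolated alternating-sign minimum-jerk offset steps
  (default 4 mm, 0.15 s) at Poisson times thinned to ≥ 0.25 s gaps; each
  step contributes an extra acceleration crossing near its centre.
  Programmed frequencies ≥ 2.5 Hz and rates > 5/s are rejected (events
  would violate the 5 Hz representability bound).

All generators are pure functions of (plan, seed); trial seeds in
`generate_experiment` are drawn from a root generator seeded by the
experiment seed, so the whole dataset is reproducible bitwise.

## Problem sizes

The test suite and the acceptance script use scaled-down protocols
chosen to exercise every code path with comfortable statistics: 100
random stroke plans for segmentation recovery, 10⁴ random profiles for
the score bound, 8 pooled one-minute trials per programmed jitter
frequency (≈ 700 events per pool), 60 s mirror trials at 200 Hz, and
2-subject × 2-phase × 2-trial experiments for the end-to-end
determinism and group-contrast checks.  A full-scale protocol (pre=40,
4×30 training, post=40 drawing trials; 11 one-minute tracking trials)
runs through the identical code paths via the manifest.

## Known limitations

* The generator models neither biomechanics nor within-phase learning;
  phase effects are step changes in plan parameters.
* Registration is linear time normalisation; landmark/continuous curve
  warping is out of scope.
* Group-level inference (mixed ANOVA, nonparametric tests, mixed-effects
  models) is out of scope by design: the pipeline emits tidy per-subject
  per-phase tables for external statistics.
* The dX/dV denominator floors and the 50 ms stimulus-match window are
  package choices where the underlying definitions are silent; both are
  configurable and logged in every run.
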