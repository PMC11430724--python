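# Methods

## The delay model and its features

The signal model at the core of the package relates the derivative of a
single EEG channel to two delayed copies of itself and one quadratic
term:

    dx/dt = a1 x(t − τ1) + a2 x(t − τ2) + a3 x(t − τ1)²

with the delays fixed in samples (τ1 = 6, τ2 = 16 at fs = 2000 Hz, i.e.
3 ms and 8 ms) and the model structure held constant throughout.  The
free parameters — the three coefficients and the least-squares error ρ —
are re-estimated on every sliding window (30 ms window, 1 ms shift) and
serve as features.  Each window is normalized to zero mean and unit
sample variance before fitting, so the features reflect the dynamics of
the signal and not its amplitude.

Estimation is ordinary least squares on the delay design matrix.  Each
window's segment carries a lead-in of `max(τ)` = 16 preceding samples so
that every in-window row has its delayed regressors defined; at an epoch
boundary, windows without a full lead-in are reported as NaN fits and
skipped by downstream aggregation (the sliding-window count formula
`floor((n − w)/s) + 1` is kept exact this way).  ρ is defined as the
root-mean-square residual, which makes it invariant to window length.
Rank-deficient windows fall back to the minimum-norm (pseudo-inverse)
solution; constant windows yield flagged NaN fits.

Two formulations are provided and tested as equal: the direct fit with
delays (6, 16) on the full-rate signal, and the interleaved
double-sampling-rate form that splits the signal into odd and even
sub-series, doubles the delays, and solves the stacked system (their
equality is a row-permutation invariance of least squares).

### Numerical choices

* **Derivative.** The default analysis derivative is a second-order
  central difference with one-sided second-order stencils at segment
  ends.  For generator/fitter consistency checks the forward difference
  `(x[t+1] − x[t])·fs` is used instead, because it is the exact inverse
  of the Euler recursion that generates the synthetic latent signal —
  with it, noiseless recovery of generating coefficients is exact to
  ~1e-11, limited only by conditioning.
* **Normalization vs. recovery.** Per-window normalization is an affine
  map under which the quadratic model is not equivariant (a window mean
  μ introduces a constant term and shifts the linear coefficient by
  2·a3·μ), so coefficient-recovery checks disable normalization; the
  classification pipeline always keeps it on.
* **Amplitude invariance.** Fits are invariant under x → c·x + b for
  c > 0 exactly; for c < 0 the normalized signal flips sign, which flips
  the sign of the quadratic coefficient while a1, a2 and ρ are
  unchanged.  The tests assert this exact form.
* **Batching.** The sliding-window path solves all windows of a channel
  through batched 3×3 normal equations (with a pseudo-inverse fallback
  for near-singular windows) and is cross-checked against the readable
  per-window reference path to ~1e-12.

## Cross-channel (triple) features

Decodable electrodes are partitioned into 20 non-overlapping triples of
neighboring channels by a deterministic greedy rule: repeatedly take the
unassigned channel farthest from the decodable set's centroid and join
it with its two nearest unassigned neighbors (ties break by label).  The
default montage is a 64-channel 10-05 cap referenced at CPz; the two
mastoids (M1, M2) and the frontal-pole midline electrode (Fpz) are
excluded from decoding, leaving 60 decodable channels.  Which channels the original
recordings excluded is not publicly documented; the choice here is a
configurable montage flag.

Per triple and window the package computes single-timeseries (ST) fits
of each channel and one cross-timeseries (CT) fit that estimates a
single coefficient vector for all three channels by solving their
stacked design matrices jointly (equivalently, summing the per-channel
normal equations).  The dynamical-ergodicity index is the ratio of the
CT error to the mean ST error: channels sharing one latent dynamic give
an index near 1; independent dynamics push it above 1.  This
construction is a documented reconstruction — the published analysis
cites a dynamical-ergodicity variant of the method whose exact statistic is not
publicly documented.

Eight per-window quantities (3 CT coefficients, CT ρ, 3 ST ρ, the
index), summarized by mean and standard deviation over a trial's
windows, give 20 × 8 × 2 = 320 features per trial.

## Classification and cross-validation

The classifier models each class as an affine low-rank subspace in
standardized feature space: class mean plus the top right singular
vectors of the centered class matrix.  A trial is scored by the residual
distance to each class subspace; the predicted class minimizes the
residual (ties break to the lexicographically first label) and the
two-class decision score is the residual difference, ranked for ROC AUC.
The default rank is the smallest explaining ≥ 90 % of the class's
variance, capped at half the available dimensions — an (almost)
full-rank basis would absorb exactly the residual complement in which
out-of-class trials are distinguished.  This construction is likewise a
reconstruction of "classification with SVD"; the cited classifier's
internals are not publicly documented.

Cross-validation is time-aware: test folds are contiguous blocks of
consecutive trials (k = 5 by default), training uses the non-adjacent
remainder with a guard gap of 2 trials on each side of the test block,
and random under-sampling equalizes class counts first.  Reported
metrics are per-fold and pooled AUC (over concatenated held-out scores)
and fraction-correct accuracy, overall and per class; per-class accuracy
feeds the relative-accuracy statistics.

## Behavioral statistics

Task accuracy is the average hit rate per participant × site × TMS ×
unit (phoneme category or individual phoneme), with missed trials
excluded from the denominator.  Relative accuracy subtracts the
site-matched sham hit rate.  The one-sided JZS Bayes factor for paired
differences places a half-Cauchy prior (default width r = √2/2 ≈ 0.707)
on the standardized effect size and integrates the noncentral-t
likelihood over it by adaptive quadrature; the reported "error %" is the
quadrature's relative error estimate × 100.  Identities used as tests:
BF₊₀ + BF₋₀ = 2·BF₁₀, BF₊₀(t = 0) = BF₁₀, monotonicity in t, and BF₊₀ → 1
as r → 0.  The two-sided factor is cross-checked against an independent
implementation (pingouin) and a dense-grid trapezoid oracle.

The decoding-vs-task-accuracy regression fits one row per participant ×
category × condition cell.  A random participant intercept is attempted
first; its variance estimate is near zero after trial averaging (the
"singular fit" situation common to such designs), in which case the
model reduces to the fixed-effects fit whose Type-III F tests
(sum-to-zero contrasts, residual denominator df) are reported.  The
recomputed p for one published row, F(9, 119) = 1.299, is 0.2446 against
a printed 0.2444 — attributable to the printed F's three-decimal
rounding — and the published Category row (F(1,135) = 2.257, p = 0.1106)
is not reproducible from the plain upper-tail F probability (0.1353),
consistent with non-integer denominator df behind the rounded integers;
no convention is guessed for it.

## The synthetic session generator

The generator emulates the study design exactly where it is stated:
two stimulation sites (lip and tongue motor cortex) with one run each,
120 trials per run (80 TMS + 40 control), a 4-consonant × 5-vowel
inventory in CV and VC order (40 pairs; 20 CV/20 VC), 500 ms
noise-immersed stimuli, and two TMS pulses at −100 and −50 ms relative
to the phoneme onset (the phoneme onset coincides with the
sound-stimulus onset, so the second pulse precedes the stimulus).  Each
order block presents every pair of its order with equal TMS and control
repetitions in a seeded pseudo-random shuffle.

The latent neural source *is* the delay model, integrated as an Euler
recursion with h = 1/fs, standard-normal initial history, and Gaussian
innovations (sd 0.01).  Category-specific coefficients place the two
phoneme classes at distinct points of the two-delay feedback loop's
damped-resonance region — bilabial (115, −175, 6), alveolar
(145, −195, 6) — chosen once for three properties: stationary amplitude
of order one, first-try divergence below ~5 % on trial-length
simulations (a bounded-retry stability guard redraws the rare divergent
trajectory from a fresh substream), and window-mean coefficient
separation of |d| ≈ 2 between classes after windowed fitting.  On
congruent TMS trials (site matches the category's articulator) the
coefficients shift outward by (∓10, ±5, 0) and the source's electrode
gain is multiplied by 1.4: per-window normalization makes the features
amplitude-invariant in the noiseless limit, so the facilitation effect
must (and realistically does) act through signal-to-noise at the
electrodes.

The forward model is instantaneous Gaussian spatial mixing centered on
the left-motor electrode C3 (σ = 35 mm, peak gain 5 µV) plus independent
1/f background noise per channel (1 µV); an optional damped-cosine TMS
artifact (10 ms, default amplitude 0) can be injected at the pulse
times.  Behavioral responses are Bernoulli draws at hit probability
base ± δ (base 0.75, matching the ≥75 % screening criterion; congruency
δ = 0.15 added on congruent and subtracted on incongruent TMS trials),
errors pick uniformly among the other three consonants, 2 % of trials
are misses, and reaction times are lognormal around 0.8 s.  The
inter-trial interval (default 3 s ± 0.5 s) and the pseudo-randomization
constraints are not publicly documented and are configuration knobs.

What the generator does **not** emulate: volume conduction and realistic
head geometry, artifacts other than the optional TMS transient (no eye
blinks or muscle), non-stationary attention or fatigue effects, acoustic
stimulus content, and any within-category phoneme structure of the
neural signal (individual phonemes differ behaviorally but share their
category's dynamics).  Passing end-to-end tests therefore demonstrates
that the pipeline recovers planted class structure and congruency
effects through this forward model — not that real EEG supports a given
decoding accuracy.

## Problem sizes used in tests

The test suite runs the full 64-channel, 2000 Hz, 120-trial-per-run
design throughout and scales only the axes the design leaves free:
end-to-end cohort checks use a 0.7 s inter-trial interval, 0.35 s epochs
anchored at the stimulus onset, and a 10 ms window shift (the default
1 ms shift is exercised by the unit tests); cohorts are 8 participants ×
10 seeds for effect recovery and behavioral-only cohorts for the
null-calibration checks.  Coefficient-recovery checks use 1 s windows at
innovation sd 0.01 (median over 20 seeds) and the interleaved-equals-
direct identity is checked on 1000 random segments.

## Known limitations

* The DE-DDA statistic and the SVD classifier are principled
  reconstructions from the method's structure, not reimplementations of
  the cited (unavailable) specifications.
* The epoch window for decoding is not publicly documented; (0, 0.5) s
  after stimulus onset is the configurable default.
* JZS "error %" reports scipy's quadrature error estimate, which is far
  smaller than the error column of JASP-style Gibbs implementations.
* Near-resonant generator regimes rely on the stability guard; extreme
  user-supplied coefficients raise a descriptive error after bounded
  retries.
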