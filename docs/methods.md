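# Methods

This note documents the models, rules and numerical choices implemented in
`tuscoda`, the parameters that matter, and what the synthetic generators do
and do not emulate.

## Accelerometer processing

Counts are vertical-axis activity counts per epoch; the epoch length must
divide 60 s. Re-integration to a coarser epoch sums complete blocks and drops
a trailing partial block (logged).

**Non-wear.** A minute is non-wear iff it lies in some window of ≥ 60
consecutive minutes in which no minute reaches 100 counts and at most 2
minutes are nonzero. Evaluation is on per-minute totals (the rule is stated
in minutes and counts/min), with epochs inheriting their minute's flag; a
trailing partial minute is never flagged non-wear. Because every sub-window
of a qualifying window also satisfies the count conditions, the union of all
qualifying windows equals the union of qualifying windows of length exactly
60, which the implementation computes with rolling sums in linear time. The
2-minute allowance treats consecutive and scattered low-count minutes
identically — the rule as stated distinguishes neither. The test suite checks
equivalence against an independent enumeration oracle.

**Intensity classification.** Cut-points are expressed in counts/min
(SB ≤ 99, LPA 100–1999, MVPA ≥ 2000) and applied at the working epoch length
by proportional scaling: with f = epoch_s/60 the bins are [0, 100·f),
[100·f, 2000·f), [2000·f, ∞). This reproduces the per-minute bins exactly at
60-s epochs and extends them consistently to 10-s epochs (SB < 100/6 ≈
16.67 counts per 10 s). Applying cut-points directly at 10 s versus
re-aggregating to 60 s first is genuinely ambiguous in the field; both are
supported (`reintegrate` + per-minute cut-points), scaling is the default.

**Valid days.** A day is valid with ≥ 10 h wear; a participant-wave is
retained with ≥ 3 valid days including ≥ 1 weekend day (Saturday/Sunday by
the local calendar date; midnight splits days). Averages over valid days are
unweighted — no 5:2 weekday/weekend weighting, since the emulated protocol
states none. Rejection is a returned value with a reason, not an exception.

## Composition assembly

Sleep duration is wake time minus bedtime, wrapping midnight when the wake
time is not after the bedtime on the clock; equal times are rejected as
ambiguous. Sleep is taken entirely from self-report and never subtracted from
device wear (devices are removed for sleep, so the two overlap by design).

The four raw durations are closed to 24 h by multiplying each part by
24/raw-sum, i.e. unaccounted (or double-counted) time is redistributed
proportionally over all four behaviours. The alternative — constraining
waking behaviours to 24 − sleep — is noted but not implemented; with ~14.4 h
mean wear plus ~9 h sleep the adjustment is small either way. Zero parts are
first replaced by 1 min (configurable) with the positive parts
multiplicatively shrunk to preserve the raw total; log-ratios need strictly
positive parts and this rule keeps closure exact.

**Exact-transfer storage.** `Composition` stores part durations as minutes
anchored into the [2048, 4096) float binade, a fixed absolute grid with
resolution 2⁻⁴¹ min (≈ 4.5·10⁻¹³ min, quantisation ~8·10⁻¹⁵ h — far below
every tolerance used). On a fixed grid, adding or subtracting any duration
that is a multiple of the grid (all practical values, in particular
10/30/60 min) is exact floating-point arithmetic, so a reallocation followed
by its reverse restores the composition bit-for-bit and untouched parts are
bit-identical. Plain float hours cannot guarantee this (an increment that
crosses a binade rounds away low bits irreversibly).

## Compositional geometry

Pivot ilr coordinates under part order (x₁…x_D):
z_j = √((D−j)/(D−j+1)) · ln(x_j / gm(x_{j+1}…x_D)), implemented via the
orthonormal contrast matrix Ψ with z = Ψ·ln x; the inverse maps z back
through exp(Ψᵀz) and closure. All logs are natural. The default part order is
(sleep, SB, LPA, MVPA); operations needing "behaviour X's first pivot
coordinate" rotate X to the front. The full coordinate set spans the same
3-space under any part order, so substitution estimates are
permutation-invariant (verified to 10⁻⁹ in the tests).

The cohort centre is the part-wise geometric mean closed to 24 h (equal to
the inverse ilr of the mean ilr vector). Its per-part CI is a log-scale t
interval for mean ln(part), exponentiated and multiplied by the point
estimate's closure factor — the construction behind published descriptive
intervals is not stated anywhere, so this documented choice is isolated in
one operation. Paired two-wave tests for a behaviour use the paired t-test on
that behaviour's first pivot coordinate; differences with near-machine-zero
spread are flagged degenerate rather than producing an undefined statistic.

## Regression and substitution estimation

Design (22 columns): intercept; 3 ilr-change columns (follow-up − baseline);
3 baseline-ilr columns; baseline marker; sex; age; 4 maternal-education
indicators (reference: no formal education); zBMI; zBMI change; 4
pubertal-stage indicators (reference: stage 1); baseline and follow-up wear
time in hours, uncentred. No covariate is standardised because the
substitution contrast needs unstandardised coefficients. Missing data are
handled complete-case with dropped identifiers logged.

**Estimators.** OLS with classical covariance σ̂²(XᵀX)⁻¹, and Huber
M-estimation (c = 1.345, ≈ 95% Gaussian efficiency) solved by IRLS with MAD
scale (median |r| / 0.6745) re-estimated per iteration, converged at relative
coefficient change ≤ 10⁻⁸ (≤ 200 iterations). The covariance is the standard
M-estimator sandwich with Huber's small-sample correction,
k²·s²·(Σψ²/(n−p))/(mean ψ′)²·(XᵀX)⁻¹; it agrees with statsmodels' RLM
standard errors to < 0.1% on the same data (cross-checked in the tests, where
statsmodels serves as an independent oracle, never as the implementation).
Zero residual scale (a perfect fit) short-circuits to the least-squares
solution with a degenerate zero covariance. Huber-IRLS was chosen over
MM-estimation because it is fully specifiable and testable from first
principles; "robust regression" alone does not pin down an estimator, so the
implemented choice is documented rather than asserted identical to any other
software's.

**Substitution estimates.** Δ̂ = cᵀβ̂ with c zero except in the ilr-change
positions, where it is ilr(reallocated base) − ilr(base); SE = √(cᵀΣ̂c); CI
uses the t quantile with df = n − p for both methods (simple, and exact for
OLS; whether published analyses used normal or t quantiles is unstated — at
n − p ≈ 274 the difference is negligible). Significance = CI excludes zero;
no multiplicity adjustment across markers or cells, matching the
CI-covering-zero convention. Infeasible reallocations (source behaviour
shorter than the transfer) are skipped, never clamped, so the estimand is
never silently changed. One model per marker.

## Synthetic generators

**Cohorts.** Baseline ilr vectors are multivariate normal (logistic-normal on
the simplex — the natural conjugate of an ilr analysis, keeping all truths
closed-form); follow-up = baseline + an independent normal change. Default
centres equal the published descriptive centres (baseline
9.13/10.89/2.93/1.05 h, follow-up 8.92/11.65/2.48/0.95 h, both summing to
24.00); per-part log-scale SDs (0.100/0.128/0.250/0.375) are calibrated so
the descriptive CIs at n = 296 match the printed interval widths, and the
change distribution uses slightly smaller SDs (no change dispersion is
published; a documented choice). Covariates follow the sample description:
49% girls, age uniform on (8.6, 17.0) years, zBMI N(0.62, 1.09²), education
and pubertal frequencies as observed, wear time N(14.43, 1.05²) and
N(14.32, 1.22²) h/day. The baseline marker is N(89.35, 27.82²) and the
residual SD defaults to 18 marker units (complement-factor scale). True
ilr-change coefficients (20, −12, 6) give 60-min reallocation effects of a
few mg/dl-scale units — illustrative magnitudes, not ground truth.
Categorical draws are conditioned on every level appearing (a ~1% reference
category would otherwise occasionally leave the design rank-deficient at
n = 296); the distortion is negligible and keeps the adjusted model
estimable. Contamination multiplies the noise of a random fraction of
outcomes by a scale factor (default 10) — symmetric variance inflation, not
mean shift, to isolate robustness from bias. Outcomes are generated by
multiplying the model module's own design matrix by the true coefficients,
so the generator and the fitted model can never drift apart.

What the generator does **not** emulate: real accelerometer measurement
error and behaviour misclassification, reactivity, school-level clustering,
assay-specific error, informative missingness, or skewed marker
distributions (markers are conditionally Gaussian). Passing recovery tests
therefore demonstrates correctness of the estimator under its own
assumptions, not robustness to these real-data features.

**Count series.** A day schedule of (label, minutes) blocks is realised by
drawing epoch counts uniformly strictly inside the scaled cut-point bins;
non-wear blocks are zeros with ≤ 2 planted sub-100-count allowance minutes.
For exact pipeline recovery the random-schedule generator enforces three
constraints that are properties of the non-wear rule, not detector defects:
non-wear blocks are ≥ 60 min (shorter ones are by definition undetectable
and would classify as SB), non-wear blocks are never adjacent to SB blocks
(an SB minute totals < 100 counts and up to two of them bordering a long
zero run are legitimately absorbed by the allowance), and SB epochs draw
counts ≥ 1 so SB minutes are never all-zero.

**Pipeline bundles.** `simulate_bundle` realises each participant-wave as
`n_days` identical scheduled days (starting on a Friday so a weekend day is
always included) plus a to-the-second-consistent sleep report, and rounds
block durations to whole minutes; refits on a bundle are therefore close to,
but not exactly, the generating truth — bundle tests assert determinism and
contracts, not recovery, which is tested on the exact cohort generator.

## Problem sizes in the tests and acceptance script

Simulation-based checks run at the emulated study's size (n = 296): 500
replicates for CI coverage (pooled over the twelve 60-min reallocations),
200 for the contamination comparison, 100 random series per epoch length for
the non-wear oracle, 100 planted schedules for exact recovery. These sizes
give Monte-Carlo error comfortably inside the asserted bands (e.g. coverage
SE ≈ 0.003 at 6000 pooled intervals against a [0.92, 0.98] band).

## Known limitations

- Sub-minute epoch cut-point scaling is one of several defensible
  conventions; results at 10-s epochs differ slightly from
  reintegrate-then-classify.
- The robust covariance is asymptotic; at small n (< ~50) its CIs undercover.
- The descriptive CI construction is a documented choice, not a published
  one.
- `filter_valid` treats the weekend as Saturday/Sunday of the local calendar
  date; shift-sleep or travel across time zones is out of scope.
- Compositions are limited to strictly positive parts above ~5·10⁻¹³ min;
  genuine structural zeros need a different treatment than the replacement
  rule.
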