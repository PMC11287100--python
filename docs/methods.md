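# Methods

This note documents the models, conventions, and numerical choices behind
`stepfit`, in the spirit of a statistical-software methods appendix.  It
states no empirical number that the test suite or `scripts/acceptance.py`
does not itself compute.

## Event model and day partitioning

A recording is a gap-free, overlap-free sequence of events per subject,
each with a start timestamp (second precision), a positive duration, one of
five activity labels (`primary_lying`, `sedentary`, `standing`, `stepping`,
`nonwear`), and a total (both-feet) step count carried only by stepping
events (minimum 2 = one stride).  Nonwear and primary lying are explicit
labels rather than inferred from gaps: sedentary time must exclude time in
bed, and wear time must exclude nonwear, so both states have to be
representable losslessly.  Contiguity is a hard validation error, not a
warning; the synthetic generator always emits contiguous series.

Days are wall-clock calendar days of the timestamps themselves — no
timezone arithmetic, since the event dialect carries none.  Events spanning
midnight are clipped; a clipped stepping piece receives steps prorated by
its duration fraction, rounded half-up.  Rounding each piece independently
conserves the series step total to within one step per midnight crossing
(the halves sum to the original except when the prorated fraction lands
exactly on .5), which partition tests assert.

## Behavior measures

- **Wear / valid days.** Wear = all non-nonwear time (primary lying counts
  as worn).  A valid day has ≥ 10 h wear (inclusive); subjects require ≥ 4
  valid days.  All `avg_*` measures are means over valid days only.
- **Intensity.** The event stream alone cannot support a metabolic (MET)
  model, so intensity uses a cadence-threshold classifier: sedentary events
  are sedentary; standing is light; stepping is light below 100 steps/min
  and moderate-to-vigorous at or above (threshold configurable).  This is a
  documented stand-in for proprietary energy-expenditure approaches: its
  MVPA minutes are not comparable in level to MET-based MVPA, but it is
  reproducible from event data and preserves ordering across subjects.
- **Stepping bouts** are maximal runs of consecutive stepping events with
  total duration ≥ 60 s (inclusive); the interruption tolerance defaults to
  0 s (strict contiguity) and is configurable.
- **Weighted median cadence** is the lower weighted median: bouts sorted by
  cadence, weighted by duration, returning the smallest cadence whose
  cumulative weight reaches half the total.  Bouts and windows are pooled
  across all valid days, not averaged per day.
- **Peak 30-s cadence** lays each stepping event's steps out at uniform
  rate on the day's 1-second grid and takes the maximum step total over all
  30-s windows at 1-s stride within each valid day, × 2 to steps/min,
  reported to one decimal.  Windows do not span midnight.  The oracle tests
  compare against exhaustive window enumeration to within half a reporting
  unit (0.05 steps/min), the precision to which the measure is defined.
- **Fragmentation.** Active bouts are maximal standing/stepping runs,
  sedentary bouts maximal sedentary runs; primary lying, nonwear, and day
  boundaries break bouts and contribute to neither.  ASTP = number of
  active bouts / total active minutes (exactly the reciprocal mean bout
  duration), SATP analogously; the Gini coefficient of sedentary bout
  durations uses the mean-absolute-difference formula.
- Undefined measures (no qualifying bout, no sedentary time, zero valid
  days) propagate as NaN into downstream statistics, which handle
  missingness pairwise-complete; nothing is imputed as zero.

## Clinical scoring

FACT-G: 27 items (7 physical, 7 social, 6 emotional, 7 functional), raw
0–4, negatively worded items reverse-scored (4 − raw).  Subscales prorate
by the instrument's standard rule (score = answered sum × n_items /
n_answered when more than half answered, else missing); the total is
missing when any subscale is.  The 5-item physical subset (energy, family
needs, pain, feeling ill, time in bed — excluding nausea and treatment side
effects) is an unprorated sum: any skipped item makes it missing, since the
crosswalk is defined on complete sums.

The PROMIS-PF linkage is a monotone integer lookup (0–20 → T score).  The
published crosswalk values are not redistributable here, so the package
ships `promis_pf_crosswalk_synthetic.csv`, a SYNTHETIC affine placeholder
(T = 19 + 2.1 × score, spanning 19–61) carrying a provenance string saying
so; real analyses should supply the published table via
`crosswalk_path` / `load_crosswalk`.  Lookup is on the integer sum score —
the only option a sum-score crosswalk supports.

Ceiling effects are the percentage of non-missing scores at the instrument
maximum, reported both rounded to integer percent (conventional
presentation) and at one decimal.  Predicted submaximal VO2 uses the
sex-specific linear equations in treadmill duration given in the README;
duration must be positive.

## Association statistics

Spearman correlations use average ranks and the t approximation
t = ρ√((n−2)/(1−ρ²)) on n−2 df — standard at n ≈ 50–90, where the exact
permutation null is unnecessary.  The partial Spearman rank-transforms all
variables, residualizes the x- and y-ranks on the covariate ranks plus
intercept by least squares, and correlates the residuals (df = n−2−k);
the unit tests verify it against an independent implementation
(`pingouin.partial_corr`).  Cancer stage enters covariate sets as ordinal
0–4; "Unsure" becomes missing and drops by complete-case exclusion.  A
rank-deficient covariate matrix raises a collinearity error naming the
offending column.

Tertile and median splits sort by value with stable input order as the tie
break, then cut by rank so group sizes differ by at most one (lower groups
absorb the remainder).  Two-sample comparisons gate on per-group
Shapiro–Wilk tests at α = 0.05: both groups compatible with normality →
two-tailed Welch *t* (Welch–Satterthwaite df); otherwise two-tailed
Mann–Whitney *U* with tie correction.  The gate is applied per compared
group — either group deviating selects the nonparametric test — the
conservative reading where per-group vs. pooled gating is ambiguous.  Holm
adjustment is the step-down ladder (adjusted_(i) = max_{j≤i}(m−j+1)p_(j),
capped at 1), applied within the narrowest defensible family: the three
pairwise comparisons of one behavior-measure × self-reported-measure
tertile analysis.  The fitness median split yields a single comparison per
measure (family of one).  Whether tertile analyses compare all three pairs
or only high-vs-medium and high-vs-low is configurable
(`tertile_pairs: all | extremes`, default all).

The reverse/rank inverse-normal (RIN) transform, Φ⁻¹((r − 3/8)/(n + ¼)) on
average ranks, is provided for plotting heavily skewed measures (MVPA
time); analyses themselves stay on the rank scale.

## Coefficient-equality comparison

Each behavior measure is regressed on one self-reported outcome, predicted
VO2, and the five covariates, with an intercept.  Standardization (z-scores
for continuous columns including the response, sum coding ±1 for sex,
ordinal-then-z for stage) happens **within each model's complete-case
set**, because each comparison is restricted to participants with no
missing values for the specific measures compared; coefficients are
therefore standardized coefficients.  The constrained model replaces the
outcome and VO2 columns by their sum (one shared coefficient, one fewer
free parameter).  The primary statistic is the nested-model
F = ΔRSS/(RSS_u/df2) on (1, n − p_free) df — for Gaussian OLS this is
order-equivalent to the likelihood-ratio statistic, and the Gaussian
log-likelihood difference is reported alongside.  The module's primary
correctness oracle, asserted over hundreds of fuzzed designs, is the exact
algebraic identity F = t², where t is the Wald statistic for the contrast
β_outcome − β_vo2 = 0 from the unconstrained fit.  The direction label
compares |β_vo2| against |β_outcome|, so "more strongly associated with
fitness" is meaningful for negatively signed measures (e.g. sedentary
time).  Stage may instead enter as categorical dummies
(`stage_as_categories`); ordinal is the default.  No multiplicity
adjustment is applied across the 7 × 4 comparison grid, matching
conventional reporting of such grids.

## Synthetic cohort generator

The generator exists because the emulated study's raw data are not
deposited; it makes every stage testable and encodes the study's
qualitative finding as ground truth.  Two standard-normal latents drive the
cohort: fitness F and well-being W with corr(F, W) = 0.15.

- **Behavior volume.**  Expected daily steps =
  exp(μ + 0.35·F + 0.05·W + ε_subject + ε_day), clipped to [1400, 17500],
  with μ set to log(6916) minus half the total log-variance so the cohort
  mean lands near the published 6916 steps/day.  ε_subject ~ N(0, 0.45²)
  and ε_day ~ N(0, 0.25²) were chosen — once — so that the *recovered
  association magnitudes* match the published pattern (steps–VO2 Spearman
  ρ ≈ 0.4–0.5; steps–well-being ρ ≈ 0.1–0.2, i.e. mostly below the n = 86
  detection threshold).  This deliberately trades away the published
  cross-sectional SD of steps (the generator's spread is wider): with the
  small behavior–well-being couplings above, no noise scale can match both
  the printed SD and the printed null associations, and the association
  structure is the scientifically load-bearing feature.  The couplings are
  configurable, so null (b_steps = 0) and reversed worlds are generable for
  error-rate studies.
- **Day structure.**  Each day: overnight lying until a ~07:06 wake, a
  waking window to ~22:18, evening lying to midnight.  Waking time is tiled
  by alternating sedentary runs and upright runs (standing segments
  interleaved with stepping events); nonwear blocks (exponential total,
  mean 36 min/day, at most two blocks) slot between runs.  About 36 % of a
  day's steps arrive in bout-length stepping events (≥ 60 s, lognormal
  durations, cadence ~ N(99 + 4F, 10) truncated at 40 steps/min — centring
  the weighted median cadence near the published 98.7), the rest in 8–45 s
  sporadic events at lower cadence.  Standing time ~ N(215, 35) min;
  sedentary time absorbs the remainder, putting the sedentary mean near the
  published 582 min/day.  All durations are integer seconds, so series
  round-trip the CSV dialect byte-exactly and every generated day is
  contiguous by construction.
- **Questionnaire.**  Each item discretizes z = λW + √(1−λ²)ε at four
  ordered cuts (λ = 0.8 for physical/functional, 0.55 otherwise; cut
  spacing 0.85).  The top cut is calibrated by quadrature + root finding so
  the expected fraction of subjects with all five subset items at maximum
  equals the 20 % ceiling target, which also produces the strongly
  left-skewed score distributions typical of the instrument.
- **Treadmill.**  T = clip(15.1 + 4·F + N(0, 2), 0.5, 25) min, giving
  corr(T, F) ≈ 0.9 and a cohort VO2 mean near 29 mL/kg/min through the
  sex-specific equations (71 % female).
- **Demographics** are drawn from truncated normals / lognormal / a
  categorical stage distribution matching the published cohort table
  (age 55.4 ± 12.9 in 21–85, BMI 27.4 ± 5.2 in 18–43, months since
  diagnosis lognormal(3.22, 0.70), stage frequencies including 8 %
  "Unsure", which later drops from covariate-adjusted analyses).

Identical config + seed reproduces byte-identical output files (a single
`numpy` Generator with a fixed draw order).

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: posture-classification error, nonwear
misdetection, missing questionnaire or treadmill data (defaults are
complete-case), day-of-week and seasonal structure, within-bout cadence
dynamics, and the published cohort's exact dispersion and range for every
measure.  Calibration is soft (cohort means near published values at
10–15 %), never claimed equality.

## Problem sizes and tolerances in the test suite

Oracle fuzzing uses 200 random series of up to 2000 events; the
coefficient-equality operating characteristics use 2000 null and 1000
power replicates at n = 86; calibration means average 20 seeded cohorts
and the end-to-end pattern is checked as a majority over 10 seeded
cohorts; `scripts/acceptance.py` uses 10 calibration and 10 headline
cohorts.  These sizes keep the full suite and the acceptance script to a
few minutes on one CPU while leaving Monte-Carlo error well inside the
asserted bands.  Exact identities (Wald ≡ F; scoring arithmetic; the VO2
equations) are asserted at 1e-8–1e-12; statistical calibrations at the
bands stated in the tests (e.g. empirical size in [0.035, 0.065]).

## Known limitations

- The intensity classifier is cadence-based, not metabolic; its MVPA level
  is lower-bounded by the 100 steps/min convention and not comparable to
  MET-based estimates.
- The shipped crosswalk is synthetic; linked T scores are placeholders
  until the published table is supplied.
- The generator's latent structure is linear-Gaussian on the log-step
  scale; it encodes the target association pattern but is not a
  biomechanical model of gait or heart-rate dynamics.
- Fragmentation bouts break at midnight, slightly inflating bout counts
  for subjects active around midnight (rare under the default day
  structure).
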