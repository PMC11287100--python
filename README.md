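# stepfit

Do wearable-derived measures of real-world physical behavior tell us how
cancer survivors are *feeling*, or how *fit* they are?  `stepfit` is a
Python package for answering that question with thigh-worn-accelerometer
event data.  It derives the standard behavior measures from event-level
recordings (activPAL-style), scores self-reported well-being and physical
function, predicts aerobic fitness from a submaximal treadmill test, and —
its core statistical contribution — tests, for each behavior measure,
whether it is more strongly associated with aerobic fitness than with
self-reported well-being, via an equality-constrained regression
comparison.

## What it computes

**Behavior measures** (per subject, averaged over valid days — ≥10 h wear;
subjects included with ≥4 valid days):

- daily sedentary time (secondary lying; time in bed excluded), light and
  moderate-to-vigorous activity time (cadence-threshold classifier,
  MVPA ≥ 100 steps/min), step count, and time in stepping bouts ≥ 1 min;
- duration-weighted median cadence of stepping bouts and peak 30-second
  cadence (maximum step total in any sliding 30-s window, in steps/min),
  both pooled across all valid days;
- activity-fragmentation metrics: active→sedentary and sedentary→active
  transition probabilities (ASTP = 1 / mean active bout duration in min;
  SATP analogously) and a Gini coefficient over sedentary bout durations.

**Clinical anchors**: FACT-G total (0–108) and physical well-being (0–28)
with standard reverse-scoring and >50 % prorating; a 5-item physical
well-being subset (0–20) linked to PROMIS-PF T scores through a monotone
crosswalk table (a clearly labelled synthetic placeholder ships with the
package); and predicted submaximal VO2 from treadmill time-to-70 %
heart-rate-reserve `T` (minutes):

    women:  VO2 = 1.38 T + 5.22      (mL/kg/min)
    men:    VO2 = 1.44 T + 14.99

**The coefficient-equality test.**  For behavior measure *y*, self-reported
outcome *s*, and fitness *v* (all standardized; sex sum-coded ±1; stage
ordinal 0–4), two nested Gaussian linear models are compared:

    unconstrained:  y = β_s s + β_v v + γ'z + ε
    constrained:    y = β (s + v) + γ'z + ε        (β_s = β_v forced)

    F = (RSS_c − RSS_u) / (RSS_u / df2),  df1 = 1,  df2 = n − p_free

For Gaussian least squares this F ordering coincides with the
likelihood-ratio ordering, and F equals the squared Wald *t* for the
contrast β_s − β_v = 0.  A significant F with |β_v| > |β_s| means the
behavior measure tracks fitness more closely than self-report.

Association analysis around it follows field practice: Spearman and partial
Spearman correlations (rank-residualization on age, sex, BMI, months since
diagnosis, stage), tertile/median splits with stable tie-breaking,
Shapiro–Wilk-gated Welch *t* / Mann–Whitney *U* comparisons, and Holm
adjustment within each three-comparison family.

Because no raw cohort is distributed, a **synthetic cohort generator**
(`stepfit.simulate`) produces event series, FACT-G responses, demographics,
and treadmill durations from two correlated latent traits (fitness and
well-being) with known couplings, calibrated to the published cohort's
summary moments.

## Worked example

```bash
stepfit simulate --seed 1 --out sim/
stepfit run --events sim/events --cohort sim/cohort.csv --out report/
```

which prints

```
wrote synthetic cohort (n=86, seed=1) to sim/
analysis complete: 86 subjects analyzed; report in report/
```

and writes `subject_summary.csv`, `distributions.csv`, `correlations.csv`,
`split_comparisons.csv`, `coefficient_comparisons.csv`, and
`run_log.json`.  For seed 1, `coefficient_comparisons.csv` contains

```
behavior_measure,outcome,n,beta_outcome,beta_vo2,F,df2,p,direction
avg_steps,factg_total,78,0.078,0.625,7.668,70,0.007,vo2
```

read: over the 78 complete cases, standardized daily step count loads on
predicted VO2 (β = 0.63) far more than on FACT-G total well-being
(β = 0.08); forcing the coefficients equal worsens the fit significantly
(F(1,70) = 7.7, p = .007), i.e. step count is more strongly associated with
aerobic fitness than with self-reported well-being.  The same run shows the
steps–VO2 Spearman correlation significant and the steps–FACT-G correlation
not (see `correlations.csv`).

The library API mirrors the CLI: `simulate_cohort`, `summarize_subject`,
`score_factg` / `link_promis_pf` / `predict_submax_vo2`, `spearman` /
`partial_spearman` / `compare_groups` / `holm_adjust`, and
`compare_coefficient_equality`; see the module docstrings.

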