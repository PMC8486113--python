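# Methods

This note documents the statistical model behind `carcmort`, the defaults
of every tunable parameter, the design of the synthetic-registry
generator, and the numerical choices and limitations a user should know
before trusting output on real data.

## Study design

The analysis is a retrospective open-cohort design over a fixed study
window (default 2009-01-01 … 2018-12-31). Each person contributes
person-time to exactly one state at a time: detention in a closed prison,
a semi-open prison, a police station, or youth detention; the community
following a release from prison (closed or semi-open); or the
non-incarcerated resident population. Facility episodes are censored at
transfer to a different facility type, release, death, or the window end;
post-release episodes at reincarceration in any facility type, death, or
the window end. Mortality rates in each state are compared with the
non-incarcerated population via directly standardized incidence rate
ratios (IRRs).

## Identity resolution and linkage

**Similarity.** For strings `a`, `b` (ASCII-folded, upper-cased,
whitespace-collapsed):

```
sim(a,b) = (1 − lev(a,b)/max(|a|,|b|)) · (min(|a|,|b|)/max(|a|,|b|))^γ
```

with `γ = 0.5` by default. The length-difference weight penalizes matches
between a short fragment and a long full name, which plain normalized
Levenshtein treats too generously. `sim` is 0 when either string is empty
and 1 only for identical non-empty strings. Edit distances come from
edlib, with a banded cutoff when only "is the similarity above x" is
needed.

**Deduplication** applies two decision trees. Records sharing an internal
ID merge when their names are highly similar (default threshold 0.90), or
moderately similar (≥ 0.6) with mothers' names agreeing (≥ 0.85). Records
with similar names under *different* internal IDs merge only when both
carry mothers' names and those also agree; a missing mother's name routes
the pair to the uncertain branch and the records stay separate. Candidate
pairs are generated by blocking on a consonant-skeleton key of each name
token; equality of blocked and brute-force clusterings is asserted in
tests on small noisy instances.

**Linkage** scores each (person, death-row) candidate by the mean of the
name and mother's-name similarities when both sides have a mother's name,
and by the name similarity alone otherwise. A death row is matched to at
most one person (best combined score; ties prefer the candidate whose last
movement precedes the death date, remaining ties are uncertain). A match
is accepted when the combined score *and* the name score clear the
threshold (default 0.90) — the mother's name can confirm or veto but never
substitute for a dissimilar name. A best match with a missing mother's
name and several perfect name competitors is *uncertain* and excluded
unless the sensitivity switch `include_uncertain` is set. Two post-linkage
filters mirror practice with real registries: accepted matches whose
person shows movement activity after the death date are rejected, and a
movement-log death event followed by later activity within a (wrongly
merged) cluster is dropped and counted in the manifest.

`select_threshold` picks the acceptance threshold from labeled pairs by
maximizing sensitivity subject to a specificity floor (default 0.995), the
specificity-first objective appropriate when false matches inflate
mortality rates directly.

## Exposure and person-time

Intervals are half-open `[start, end)` at day resolution: the day of a
transfer counts toward the destination. Person-years divide day counts by
365.25. Episodes longer than a per-location cap (defaults: police 30 days,
semi-open 2 years, youth 3 years; or an empirical-quantile rule) are
truncated with reason `truncated`, compensating for unreported releases
from those facility types; closed-prison episodes are never truncated.
Episodes splitting across calendar years or release anniversaries are cut
exactly at the boundary, so person-time totals are conserved under any
stratification (asserted to 1e-9 in tests).

## Age structure

Custody age structure arrives as annual wide-bin proportions per sex. A
negative binomial (size–mean parameterization) truncated and renormalized
over integer ages `[14, 95]` is fitted to each table by maximizing the
multinomial likelihood of the bin masses (Nelder–Mead, multistart over
size ∈ {1, 5, 20, 80}, tolerance 1e-8; fits with < 3 positive bins or
parameters at bounds are refused or flagged). Fitted single-year masses
are then rescaled within each wide bin so bin totals equal the reported
proportions exactly.

Custody person-time per (sex, facility, calendar year) is spread over
single years of age by that year's fitted distribution; closed prisons,
semi-open prisons, and police stations share one structure per sex-year.
Youth detention has no age-structure information and is analyzed as crude
rates only. Post-release person-time per (sex, release year, years since
release) uses the release year's custody structure aged forward one year
per elapsed year; the cohort's modeled person counts are then depleted by
the observed age-specific death counts (half a year in the death year, a
full year in each later year, floored at zero) and each cell's observed
person-time is re-spread over the depleted age profile, so cell totals are
conserved. The non-incarcerated denominator disaggregates the projected
general-population tables the same way and subtracts custody person-time
plus community person-time after release from *any* facility type.

Standardization uses 4-year bins from age 18 (18–21, 22–25, …, top bin
open); deaths with missing or under-18 ages are excluded from age-based
analyses (and counted in the manifest) but retained for all-cause hazard
analyses.

## Rates and inference

* Single rate: exact Poisson CI via chi-square quantiles,
  `[χ²(α/2, 2d)/2, χ²(1−α/2, 2d+2)/2] / Y`.
* Directly standardized rate `ASR = Σ w_a d_a/Y_a`: Fay–Feuer gamma CI
  with variance `Σ (w_a/Y_a)² d_a`.
* Two-sample rate ratio: exact conditional construction. Given `d₁+d₀`,
  `d₁ ~ Binomial(n, Y₁ρ/(Y₁ρ+Y₀))`; Clopper–Pearson limits for the
  binomial proportion are inverted for ρ. `d₀ = 0` flags an unbounded
  upper limit. Tests verify agreement with brute-force tail inversion to
  1e-6 over a grid of counts up to 50.
* Standardized rate ratio: each ASR is condensed to an equivalent count
  `D = ASR²/Var` and equivalent person-time `T = D/ASR`, then the
  exact-Poisson-style F limits are applied:
  `lower = D₁/(D₀+1) · (T₀/T₁) / F_{1−α/2}(2(D₀+1), 2D₁)` and the mirror
  image for the upper limit. There are several published F-based variants;
  this one reduces to the exact conditional interval in the single-stratum
  case (verified in tests) and achieves ≥ 0.95 empirical coverage at a
  true ratio of 2 in 1,000-replicate simulations. The implementation is a
  single function and deliberately swappable.
* No multiple-testing adjustment is applied; results are presented as
  estimates with CIs.

## Hazard and survival

The instantaneous death rate over exposure time is estimated by a
P-spline: events and person-time are accumulated on a monthly grid, and a
cubic B-spline on the log hazard is fitted by penalized Poisson IRLS with
a log-exposure offset and second-difference penalty. The smoothing
parameter is bisected to a target effective df (default 4) or chosen by
AIC over a λ grid. Pointwise 95% bands use the Bayesian posterior
covariance `(X'WX + λP)⁻¹` of the spline coefficients, which is better
calibrated pointwise than the frequentist sandwich. Competing causes are
censored, giving cause-specific hazards; violence and suicide are pooled
for post-release curves and separable by configuration for in-custody
curves. Deaths present only in the movement log (no registry match) enter
all-cause hazards but no cause-specific or age-based analysis.

Kaplan–Meier estimation and the k-sample log-rank test delegate to
lifelines; an explicit risk-set-walk product-limit oracle backs the tests.
The reduced release cohort keeps men whose last prison release precedes
the window end by ≥ 5 years, censors follow-up at 5 years (and at
reincarceration), computes cumulative prior incarceration across all
facility types, and stratifies by boundaries at 0.5 and 2 years.
Age-adjusted survival analysis is *not* attempted — individual ages are
unavailable in movement-log data — only within-age-group description.

## The synthetic-registry generator

Careers are a continuous-time Markov jump process over {never, closed,
semi-open, police, youth, released}; mortality is a competing exponential
clock with intensity `baseline(age, sex) × RR(state, years-since-release)`.
Piecewise-constant intensities are simulated exactly by restarting clocks
at age-band edges, release anniversaries, and the youth/adult threshold.
Defaults (all configurable in one YAML file):

* window 2009–2018; sex ratio 0.92 male; population n per run as stated
  below;
* population pyramid: near-uniform density over ages 4–95, including a
  child bin (ages 4–13) whose members age into arrest eligibility during
  the window, keeping the population quasi-stationary across the decade;
* arrest intensity 0.05/year times an age profile peaking at 25–29
  (multiplier 3.4) and falling to 0.07 above 60 — this, not the pyramid,
  produces the young-adult-heavy custody age structure administrations
  report; arrests below 18 go to youth detention, none below 12;
* facility dynamics (events/person-year): police exit ≈ 40 (split between
  transfer to closed and release), closed: transfer to semi-open 0.5,
  release 1.2; semi-open: release 3.5, transfer back 0.5; youth release
  1.1 with administrative release at 18; reincarceration 0.25,
  age-independent — so a release cohort's age profile truly is the
  release-flow profile aged forward, which is exactly the assumption the
  estimator makes;
* baseline mortality: banded male/female schedules from 30/100k (children)
  to 13,000/100k (80+), with the male young-adult external-cause hump;
* state rate ratios: closed 1.3, semi-open 2.4, police 3.1, youth 8.1,
  post-release a piecewise-constant schedule by integer year since release
  (default constant 3.0, so the standardized post-release IRR has a single
  configured truth);
* cause mixes per state over {violence, suicide, communicable,
  noncommunicable, transport, other}, realized as representative ICD-10
  codes; 10% of in-custody male violence deaths are certified Y20
  ("hanging, undetermined intent") to exercise the reclassification rule;
* name noise: per-character corruption probability with
  substitution/deletion/insertion weights, token drop/swap, missing
  mother's name probability, duplicate-internal-ID probability — all zero
  by default;
* in-custody deaths are recorded in the movement log with probability 0.6,
  emulating state under-recording; all deaths reach the mortality registry
  by default.

The generator emits the four inputs the analysis needs (movement log,
mortality registry, annual custody age tables computed from realized
adult-facility person-time, and a projected-population table computed from
realized resident person-time) plus a truth table binding every row to its
generating individual.

**What the generator does not emulate.** Real name-error distributions are
unknown; the noise model is free configuration, not calibration. Sex is
carried as a column (real movement logs require inference from facility
information and manual review). Migration out of state, socioeconomic
confounders, court events beyond ignorable "other" rows, and
cause-of-death misclassification in custody are absent. Reincarceration is
age-independent by design; where real recidivism declines with age, the
release-cohort aging model is misspecified in exactly the way it is for
the real data, and rate ratios at the oldest ages inherit that
uncertainty. Passing tests therefore demonstrate correctness of the
estimator under its own assumptions, not robustness to every failure mode
of real registries.

## Problem sizes

The test suite exercises parameter recovery on cohorts of 12,000
individuals across ten seeds (the standardized IRR CIs must contain the
configured truths in ≥ 90% of seeds), linkage exactness on zero-noise
cohorts of 4,000, and hazard recovery pooled over ten replicates of 20,000
subjects. The acceptance script runs one cohort of 30,000. These sizes
give Poisson counts comparable to the motivating study's custody death
tallies while keeping a full run in minutes on one CPU; all are
configuration, not constants.

## Known limitations

* The exact thresholds, truncation caps, and bin bounds of the motivating
  analysis are not published; all are configurable with the defaults
  documented here, and every run's manifest records the values used.
* The wide-bin disaggregation cannot see within-bin age drift; the
  generator's quasi-stationary population keeps this error small, but on
  real data from a rapidly changing prison population it need not be.
* The non-incarcerated denominator retains the pre-arrest person-time of
  future arrestees (their pre-arrest deaths are likewise retained), so the
  reference rate carries a small healthy-future-arrestee distortion
  inherent to the subtraction design.
* Uncertain matches are excluded by default; the `include_uncertain`
  switch quantifies the sensitivity of every rate ratio to that choice.
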