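# Methods

## The design being emulated

The package implements the analysis pipeline of an active-comparator,
new-user cohort study on administrative claims, the design used to
emulate cardiovascular outcome trials and to extend them to routine-care
populations. Cohort entry is the first dispensing of either study drug
after a drug-free washout; confounding by indication is addressed by 1:1
propensity-score matching; follow-up is as-treated; absolute risks,
risk differences and hazard ratios are estimated per database and pooled;
and, where a reference randomized trial exists, the emulation is scored
against it with four binary agreement metrics.

## Synthetic claims model

The generator emulates the statistical structure the analysis assumes,
not any real vocabulary or database.

* **Covariates.** Binary covariates are Bernoulli with configured
  prevalence and leave a coded diagnosis trace uniformly in the year
  before index, so the assessment stage can rebuild them from claims
  alone. Count covariates are Poisson (capped at 10); age is a rounded
  normal clipped to 30–95 years and materialised as `birth_year`
  (day 0 of the study epoch = 2018-01-01). Model-scale transforms:
  binary/count enter raw; age enters as (age − 60)/10.
* **Assignment.** Logistic channeling
  P(exposure | x) = expit(α + xᵀγ). With γ = 0 assignment is
  randomized-like.
* **Events.** Each outcome component (myocardial infarction, stroke,
  death, negative controls) has an independent latent exponential time
  with hazard λ₀·exp(xᵀβ + θ·treated), measured from index. Death is
  terminal: later events are truncated. Constant hazards are the
  simplest model consistent with proportional-hazards reporting; they
  make the conditional HR of any composite exactly e^θ when every
  component shares θ.
* **Exposure.** Fills of one drug code per arm, fixed days-supply;
  discontinuation is geometric per refill cycle (per-cycle stop
  probability 1 − (1 − r)^supply from the per-day rate r), independent
  of covariates by default. Optional knobs add switches to the other
  study drug, same-class starts, and prior same-class use that violates
  the washout.
* **Enrollment.** A single span from day 0; with configured probability
  the span ends at a random day in the first post-index year
  (disenrollment). All intervals are half-open `[start, end)`.

### Preset scenarios (the study conditions)

| preset | n/database | databases | true θ (CV components) | channeling |
|---|---|---|---|---|
| `null` | 20,000 | 1 | 0 | none |
| `confounded_benefit` | 20,000 | 1 | ln 0.8 | strong (established CVD −1.5, age −0.25/decade) |
| `benchmark_like` | 50,000 | 3 | ln 0.85 | moderate |

`confounded_benefit` raises component hazards (MI 9·10⁻⁵, stroke
7·10⁻⁵, death 5·10⁻⁵ per day; established CVD multiplies the CV hazard
by 3) so one 20,000-patient database yields on the order of a thousand
composite events — enough for a stable Cox fit — while the channeling
coefficient −1.5 on a 35%-prevalence covariate produces a pre-matching
SMD near 0.7, far beyond the 0.10 adequacy threshold.
`benchmark_like` instead targets the ~1–2%-per-year composite risk of a
cardiovascular outcome-trial emulation across three database replicates.
Negative controls (lumbar radiculopathy, abdominal hernia) always have
θ = 0 exactly. Discontinuation (0.0045/day, both arms) gives a median
on-treatment time near half a year, so discontinuation is the modal
censoring reason, as in real claims cohorts.

### What the generator does not emulate

Real code vocabularies and code-list algorithms; measurement error and
imperfect endpoint positive predictive value; unmeasured confounding
(channeling acts only through modeled covariates, which is exactly what
lets matched analyses recover the truth); covariate-dependent
discontinuation by default; seasonality, calendar trends, or duplicate
patients across databases (replicates are independent). Passing tests
therefore demonstrate correctness of the *pipeline*, not robustness of
the design to violations it cannot see.

## Analysis conventions

Choices the design left open, fixed here and asserted in tests:

* **Washout** is assessed against exposure, comparator *and* same-class
  codes over `[index − 365, index)`: "new user" means new to the whole
  class comparison. Same-day dual initiators cannot be assigned an arm
  and are excluded (logged in attrition).
* **Enrollment** requires a single half-open span covering
  `[index − 365, index]`; age is index year minus birth year
  (claims-grade coarse age).
* **Risk tiers**: high = age ≥ 50 with an established-CVD code in
  lookback; moderate = age ≥ 60 with a subclinical marker; else low.
  Code sets are configuration, not hard-coded vocabularies.
* **Baseline windows** are half-open `[index − w, index)`: index-day
  events are post-baseline.
* **SMD** uses the pooled (unweighted average) variance denominator and
  is reported as an absolute value; zero variance in both arms with
  equal means is 0, with unequal means +∞ (warned).
* **Matching** is greedy nearest-neighbor without replacement in a
  seeded random order over exposure members; gap ties resolve to the
  lowest comparator id; caliper 0.01 on the probability scale. Greedy
  matching can be smaller than the optimal maximum matching; tests bound
  it by the maximal-matching guarantee (≥ half the optimum) and verify
  exact agreement on small fixtures. Matching runs within each database;
  analyses are pooled afterwards.
* **Follow-up** starts the day after index ("52 weeks" = 364 days;
  events on the index day are history, avoiding immortal-time
  ambiguity). Censoring hierarchy: endpoint > discontinuation (episode
  end = last chained supply end + 45-day grace) > switch > same-class
  start > disenrollment > window end; on an exact day tie the endpoint
  wins. Same-day composite components resolve by severity
  (death > myocardial infarction > stroke). The as-started contrast
  drops the treatment-related censoring rules and can only lengthen
  follow-up. Deaths after a censoring date are not counted.
* **Estimators.** KM and Aalen–Johansen are computed exactly on the
  integer-day grid (claims data are heavily tied; the test suite
  cross-checks both against lifelines). Composites that include death
  use KM; nonfatal composites use Aalen–Johansen with death competing,
  and their Cox fits are cause-specific (competing deaths censor).
  Cox uses the single arm indicator, Efron ties by default (Breslow via
  argument), Newton–Raphson with step-halving, gradient tolerance
  10⁻¹⁰, iteration cap 60; a zero-event arm yields a flagged
  infinite-estimate signal rather than a number. Wald CIs use
  z = 1.959964.
* **Bootstrap.** Risk-difference CIs are percentile (2.5/97.5) over
  patient-level resamples with replacement *within arm* of the analytic
  (matched) cohort; matching and propensity scores are not re-estimated
  per replicate. Replicates default to 1,000 and are seeded.
* **Pooling** is fixed-effects inverse variance on the log-HR scale.
* **Agreement.** Z is computed on the log-HR scale with SEs recovered
  from CI widths as (ln U − ln L)/(2·1.959964); the printed 1.96 is the
  agreement cutoff. Statistical agreement means both estimates
  significant on the same side of the null *or* both non-significant;
  it is assessed for primary endpoints only.

## Numerical and degenerate-input handling

Perfect separation of the propensity model (fitted probabilities
matching arm labels to <10⁻³) raises an explicit error advising
covariate pruning; quasi-separation warns and names suspect covariates;
constant columns are dropped with a log message. Empty arms, empty
estimate lists, non-positive calipers, and fewer than two bootstrap
replicates are rejected with named-field errors. Pipeline pooling
degrades gracefully: databases whose endpoint had no events contribute
a flagged placeholder and are excluded from the inverse-variance sum.

## Problem sizes used by the test suite

The suite runs the confounded scenario once at its preset size
(20,000 patients) for balance restoration and parameter recovery; the
oracle counterfactual hazard ratio is simulated directly from the hazard
model at n = 200,000 with both arms forced per patient. Null-scenario
CI coverage uses 100 replicates at n = 2,000; bootstrap coverage of the
risk difference uses 200 simulated datasets of 400 patients per arm at
200 bootstrap replicates. These sizes give Monte-Carlo error small
enough for the stated bounds while keeping the default test run fast.

## Known limitations

Single-covariate Cox only (the arm indicator; no covariate adjustment
beyond matching, no proportionality diagnostics). Greedy matching is not
optimal matching. The bootstrap conditions on the realized matched
cohort rather than re-matching per replicate, so its CIs do not carry
matching uncertainty. The generator's constant hazards cannot express
early-vs-late treatment effects. Database replicates share one
generating law, so fixed-effects pooling is exactly correct here —
heterogeneity statistics are out of scope.
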