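# Methods

## The study design this package implements

The pipeline implements an active-comparator new-user cohort design for
comparative vaccine safety: recipients of a target vaccine brand (adenovirus
vectored, e.g. ChAdOx1-S or Ad26.COV2.S) are compared with recipients of a
comparator brand (mRNA, e.g. BNT162b2 or mRNA-1273) for rare thromboembolic
outcomes and thrombosis-with-thrombocytopenia syndrome (TTS) in the 28 days
after vaccination. Because brand receipt is not randomised, the comparison is
adjusted by propensity-score matching on measured baseline covariates;
residual (unmeasured) systematic error is quantified with negative-control
outcomes and removed by empirical calibration; database-specific estimates
are pooled by random-effects meta-analysis.

### Cohorts and follow-up

Eligibility: adults (>= 18 years at first dose), at least 365 days of
observation before the index vaccination, a recorded brand for every
vaccination, complete age and sex, and exclusion of people whose two doses
are <= 14 days apart (presumed recording errors). The index date is the day
of the defining dose; follow-up covers days (index, index + 28], censored at
death or end of observation, so an event on the index day itself is never
counted and person-time per subject is at most 28 days. Calendar time is an
integer day index (day 0 = study start); index year and month for the
covariates derive from it with 365.25-day years and equal-length months,
which preserves ordering and day arithmetic without real-date ambiguity. Age
is index calendar year minus birth year.

### Outcomes

An outcome is a set of event concepts; composites (venous thromboembolism =
deep vein thrombosis or pulmonary embolism; arterial thromboembolism =
ischaemic stroke or myocardial infarction) take the earliest member event.
Ascertainment is first-event-only within the risk window. For each outcome,
people with any member-concept event before the index date are excluded
before matching, so matched participant counts differ per outcome.

TTS: a thromboembolic event in the risk window with concurrent
thrombocytopenia — a diagnostic code or a platelet measurement strictly
below 150 x 10^3/uL — within +/-10 days of the event. The thrombocytopenia
evidence may fall outside the 28-day window; only the thromboembolic event
must be inside it. Sensitivity variants tighten the concurrency window to
+/-5 days or the platelet threshold to 100 x 10^3/uL. When the first
in-window thromboembolic event lacks concurrent thrombocytopenia the person
does not count as a TTS case (first-event-only, consistent with the other
outcomes).

### Propensity model

Large-scale L1-regularised logistic regression of target-brand receipt on
all baseline covariates (age, 10-year age bands, sex, index year and month
indicators, condition flags from all prior history, 180-day utilisation
counts, and the Romano-Charlson and CHA2DS2-VASc summary scores). The
objective is the penalised log-likelihood l(beta) - lambda * sum|beta_j|
with the intercept unpenalised. Features are standardised internally for
the solver (the glmnet convention) and coefficients are reported on the raw
scale; raw-scale L1 on mixed binary/continuous columns conditions the
optimisation badly without changing the model class. lambda is chosen by
k-fold (default 10) cross-validated held-out log-likelihood on a log-spaced
grid descending from lambda_max, the smallest penalty that zeroes every
slope. After each fit the unpenalised intercept is polished to its exact
1-D conditional MLE; the stochastic solver otherwise leaves it short of the
optimum at strong penalties.

### Matching

Greedy caliper matching on the logit propensity score. The caliper is 0.2
pooled standard deviations of the logit (both arms pooled). The smaller arm
is the base side; when the target arm is larger, matching reverses and
comparators are matched to targets.

The matched ratio is uniform: R = max(1, min(4, floor(n_candidates /
n_base))), with matching in rounds 1..R — each round visits base subjects in
a seeded random order and assigns the nearest unmatched candidate within the
caliper (distance ties broken by lowest person id) — and only sets that
complete all R candidates are kept. The uniform completed ratio is a
deliberate design choice: a per-base "best effort" ratio concentrates extra
candidates wherever candidates are locally plentiful, which is precisely
where the propensity distributions differ, and measurably destroys the
covariate balance the matching exists to create (post-match max |SMD| of
0.3-0.4 versus 0.01-0.03 with the uniform rule, under moderate confounding
at ~20 000 per arm). With a uniform completed ratio the matched candidate
count is exactly R times the base count in every propensity region, so the
matched arms have proportional propensity distributions by construction.
Dropping incomplete sets is equivalent to trimming regions of poor
candidate support. The matched analysis is unweighted: every matched person
contributes their own events and person-time.

### Diagnostics and their consequences

1. **Measured confounding**: every covariate's post-match standardised mean
   difference, SMD = (mean_t - mean_c) / sqrt((var_t + var_c)/2) (binary
   variance p(1-p)), must be strictly below 0.1. Failure kills the
   database-specific analysis and excludes the database from pooling.
2. **Power**: the minimum detectable rate ratio (MDRR) at alpha = 0.05 and
   80% power, solved by bisection from the Wald power condition on expected
   counts. MDRR > 5 suppresses the database-specific estimate; the cell
   still contributes to meta-analysis. The expected-count Wald model is
   slightly anticonservative when expected events fall below ~200 (the
   simulated power at the reported MDRR can be up to ~1 percentage point
   short of 80%).
3. **Unmeasured confounding**: the fraction of estimable negative controls
   whose uncalibrated 95% CI excludes 1 must be strictly below 20%
   (two-sided, judged on uncalibrated CIs — calibrated CIs would make the
   diagnostic circular). Failure demotes the database's results to
   "calibrated-only".

### Estimation

Incidence rates per 1000 person-years with exact (chi-square) Poisson CIs;
the incidence rate ratio in closed form (identical to Poisson regression
with an arm indicator and log person-time offset), Wald CI and p-value;
person-time censored at the first event; 365.25 days per year. Arms with
zero events are flagged not estimable — no continuity correction, matching
the reporting convention of suppressing non-estimable cells. The incidence
rate difference (per 1000 person-years) uses a Wald CI from the Poisson
count variances; the 28-day absolute risk difference per 100 000 vaccinated
converts each arm's rate to a cumulative risk 1 - exp(-rate * 28/365.25)
and propagates the variance by the delta method. Stratified analyses (10-year
age band x sex) run the same chain per stratum and suppress strata with
MDRR > 5.

### Empirical calibration

Negative-control log-RR estimates theta_i with sampling SEs tau_i are
modelled as draws from Normal(mu, sigma^2 + tau_i^2); (mu, sigma) are fitted
by maximum likelihood over (mu, log sigma) (Nelder-Mead, sigma floored at
1e-8), requiring at least 5 estimable controls — fewer controls leave the
analysis uncalibrated, flagged as such. Calibrated quantities:
p = 2(1 - Phi(|theta - mu| / sqrt(sigma^2 + tau^2))) and
CI = exp(theta - mu +/- 1.96 sqrt(sigma^2 + tau^2)). Calibration assumes the
systematic error of the outcome of interest is exchangeable with that of the
negative controls and independent of true effect size (null-based
calibration only; no positive-control synthesis).

### Meta-analysis

DerSimonian-Laird method-of-moments pooling of the per-database log rate
ratios, with tau^2 truncated at zero, and I^2 = max(0, (Q - (k-1))/Q). A
heterogeneity warning is attached (not an automatic suppression) at
I^2 > 60%. Databases enter the pooling iff they passed the balance
diagnostic, regardless of the power or negative-control gates. The pooled
estimate is calibrated against a null fitted to *pooled* negative controls
(each control meta-analysed across databases first); pooling the
per-database calibrated estimates instead is available as
`meta.pool_calibrated_estimates`.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes, not
any particular real database:

* covariates: age ~ Normal(52, 17) truncated to [16, 95]; 54% female;
  comorbidity flags (hypertension 25%, diabetes 10%, cancer 5%, heart
  failure 3%, vascular disease 6%, stroke history 2%); 6-month utilisation
  counts Poisson(3 / 1.2 / 2) for drug/procedure/measurement records;
* assignment: one first dose per person, target-brand probability logistic
  in the covariates (confounding arises when the same covariates carry
  outcome hazard ratios); second dose of the same brand for 80%, 21-84 days
  later; optional knobs inject brand crossovers, short dose gaps,
  unspecified brands and missing demographics to exercise the eligibility
  rules;
* outcomes: per-person Poisson processes, log-linear in the covariates,
  with the target-vs-comparator true rate ratio applied inside the 28-day
  post-vaccination window only; defaults put thromboembolic outcomes at
  0.7-5 per 1000 person-years, the magnitudes seen in matched covid-19
  vaccination cohorts;
* negative controls: configurable count at a common baseline rate with true
  rate ratio 1. Defaults use 80 per 1000 person-years — the most common
  primary-care negative-control outcomes — so their estimates are precise
  enough to inform the empirical null (an NC sampling SE far above sigma
  makes the null unidentifiable in any analysis, real or simulated);
* systematic error: one multiplier per outcome, exp(Normal(mean, sd)) on
  the log scale, applied to the target arm's event intensity for all
  outcomes including negative controls — exactly the error structure the
  empirical null models;
* platelet measurements: around thrombosis-type events with probability
  0.8, offset within +/-7 days; values Normal(250, 50) x 10^3/uL, or
  Normal(90, 30) floored at 5 for the low fraction (0.3), spanning both the
  150 and 100 thresholds; a 5% background measurement rate;
* censoring: a single exponential hazard from the index date (default
  0.05/year) capped at the data horizon, with 30% of early exits recorded
  as deaths.

What the generator does **not** emulate: real concept vocabularies,
database-specific ascertainment differences (a single capture story rather
than hospital-vs-primary-care models), country-specific rollout timing,
seasonality, or correlated covariate structure beyond the shared
assignment/outcome effects. Passing tests therefore demonstrate the
statistical machinery is correct under the stated error model, not that any
real database satisfies that model.

## Validation experiments and problem sizes

All replicate counts and cohort sizes below are the package's own study
conditions, chosen to make each check informative while keeping the default
suite quick to run; the pass criteria are properties of the method.

* **Null recovery**: 100 simulated negative-control estimates at
  (mu, sigma) = (0.2, 0.1); the MLE must land within 3 asymptotic SEs.
* **Coverage restoration**: 120 000 persons per replicate, one outcome at
  45/1000 person-years with true RR 2, 50 negative controls at 80/1000
  person-years, injected bias N(0.1, 0.05^2); 200 replicates in the test
  suite (100 in the acceptance script). Uncalibrated 95% CI coverage falls
  to roughly 78% (< 85%); calibrated coverage returns above 90%.
* **Balance**: 40 000 persons (roughly 20 000 per arm), assignment log-odds
  at most 0.4 per covariate, 50 seeds; post-match max |SMD| < 0.1 must hold
  in at least 95% of seeds.
* **End-to-end recovery**: two databases of 40 000 persons per replicate,
  one outcome at 5/1000 person-years with true RR 1.33 under measured
  confounding, 15 negative controls, 60 replicates; the pooled calibrated
  95% CI must cover 1.33 in at least 90% of replicates. This configuration
  reuses the comparison-level matched set across outcomes
  (`rematch_per_outcome=False`); the default pipeline re-matches per
  outcome after prior-history exclusion.
* **MDRR**: the bisection solution is checked against an inversion of
  simulated Wald-test power (10 000 Poisson replicates per candidate) at
  three settings with 150-800 expected events, within 2 Monte-Carlo SEs.

## Numerical conventions and degenerate inputs

* Zero pooled logit SD gives caliper 0; exact ties still match, broken by
  lowest person id.
* SMD with zero variance in both arms is 0 when the means agree and flagged
  undefined (gate-failing) otherwise.
* Poisson CIs: lower bound 0 at zero events; ratio not estimable when
  either arm has zero events; MDRR not estimable at zero total events and
  monotone decreasing in person-time.
* fit_null is deterministic (derivative-free optimisation from a fixed
  start); all simulation seeds derive from a master seed by stable hashing
  (blake2s), so adding a comparison or database does not perturb existing
  results.
* The spec-level worked example for the 28-day absolute risk difference
  evaluates the closed form on rates rounded to two decimals, as a reader
  reproducing a results table would; unrounded cells shift the value by
  ~0.02 per 100 000.

## Known limitations

* Unweighted variable-ratio matching is only balance-preserving with the
  uniform completed-ratio rule used here; arbitrary per-base ratios would
  require weighting, which the design deliberately avoids.
* The empirical null assumes normal, effect-independent systematic error;
  heavy-tailed or outcome-dependent bias is not modelled.
* The MDRR's expected-count Wald approximation is mildly anticonservative
  below ~200 expected events.
* Calibrated coverage is restored to slightly below nominal (about 92-94%
  with 50 negative controls) because sigma carries estimation error that
  the calibrated interval does not propagate; this matches the behaviour of
  null-based calibration generally.
* The 20% subsampling option reproduces a compute-saving convention for
  very large claims databases and is applied after eligibility filtering.
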