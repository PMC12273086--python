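# Methods

This note records the statistical model, the synthetic-data design, and
the numerical decisions behind `psyews`, in the spirit of a model
documentation page: what is assumed, what is tunable, and what the test
suite does and does not demonstrate.

## Cohort construction

A patient qualifies if some 180-consecutive-day window, ending strictly
before their first psychiatric hospitalisation, contains ≥5 CGI-S and ≥5
GAF ratings. Decisions where several conventions were defensible:

- **Which window.** When several windows qualify, the *earliest* is used
  (one window per patient). Earliest maximises post-window follow-up and
  is reproducible; anchoring at maximal rating density would be an equally
  valid convention but is harder to audit.
- **Candidate starts.** Only observed rating days are scanned: any
  qualifying window can be slid left until its start touches an
  observation without losing observations, so the scan is O(visits) and
  provably finds the earliest qualifying window (property-tested against
  an exhaustive integer-day scan).
- **Boundaries.** The window is the closed interval `[start, start+179]`;
  a rating on the end day is inside; the outcome clock starts the day
  after. A hospitalisation `t` days after the window end with `0 < t ≤ 180`
  is an event at `t`; otherwise the patient is censored at
  `min(last visit − window_end, 180)`, floored at zero. Patients whose
  last visit falls inside the window are retained with censoring time 0 —
  they contribute no risk time but remain countable.

## Predictors

tRMSSD is implemented as the root mean square of *per-day rates of
change*, `sqrt(mean(((x_{i+1}−x_i)/Δt_i)²))`. The alternative convention
`sqrt(mean(Δx²/Δt))` is available via `method="sqrt_dt"` but is not the
default: the rate form is the natural "time-adjusted" RMSSD and its
magnitude is consistent with instability values on the order of a few
hundredths (CGI-S) to a few tenths (inverted GAF) per day at
days-to-weeks visit spacing. Same-day duplicate ratings are averaged
before differencing (a zero gap leaves a rate undefined). Instability of
the inverted GAF equals instability of the raw GAF (|Δ(100−g)| = |Δg|);
the inversion matters only for the severity mean.

Organisation-level hospitalisation propensity enters as
`logit((events + 0.5)/(n + 1))` computed on the organisation's own cohort
outcomes — the continuity correction keeps small, event-free
organisations finite. In external validation the rates are recomputed on
the validation organisations' own cohorts; this mirrors "adjusting for
local propensity" but leaks the validation outcome distribution into one
covariate, a known caveat of this adjustment style.

## Model

Cox proportional hazards, Efron tie handling (ratings and outcomes are
day-granular, so ties are common), Newton–Raphson as implemented in
lifelines. Continuous predictors (the four metrics, age, and the org
log-odds when present) are standardized with derivation-split constants
that are frozen into the saved model; validation data is never
standardized with its own moments. Square-root transforms of the two
instability predictors are applied to the raw values before
standardization and kept only if they strictly lower the AIC, each
variable assessed separately; this selection is repeated inside every
optimism-bootstrap resample so that the correction covers all data-driven
modelling steps.

Absolute risks are `1 − S₀(180)^exp(β'z)` with `S₀(180)` the Breslow-type
baseline survival re-referenced to a zero covariate vector.

Numerical guards:

- a design column with a single distinct value is dropped and recorded
  (this is also the path by which the adjusted model collapses to the
  unadjusted one when all org rates coincide);
- rank deficiency of the *centered* design raises an error naming a
  near-collinear pair (the Cox likelihood is translation-invariant, so
  collinearity-with-intercept must be checked after centering);
- a binary indicator whose on- or off-group contains no events has no
  finite maximum-likelihood coefficient (monotone likelihood); it is
  excluded from the fit with a warning and recorded in
  `dropped_columns`. This occurs routinely for the tiny unknown-gender
  category in small simulations;
- if the default Newton step diverges (near-collinear severity pairs can
  overshoot), the fit is retried with a damped step (0.1), which reaches
  the same maximum;
- `fit(tol=...)` tightens the stopping rule; the terminal parameter error
  is about `sqrt(2·tol)` because the solver tests the Newton decrement
  before applying the final step.

The proportional-hazards check is the Grambsch–Therneau scaled-Schoenfeld
score test with the identity time transform by default (the Kaplan–Meier
transform is available). Per-covariate statistics match lifelines
exactly; the global statistic `d·u'Vu / Σ(g−ḡ)²` (u the
transform-weighted sum of Schoenfeld residuals, V the coefficient
covariance, d the event count, df = number of covariates) uses the
classic averaged-information form. R's `survival::cox.zph` (≥3.0)
computes an exact per-event variance and gives slightly different
chi-squares on the same data; the two agree closely in calibration (the
null distribution of the global p is uniform — property-tested).

## Validation statistics

- **c-index**: Harrell's estimator for right-censored data; risk ties
  count ½ (checked against exhaustive pair enumeration, including tied
  event times).
- **Optimism correction**: apparent c minus the mean over B bootstrap
  resamples of (c on resample − c of the resample-trained model on the
  original data); resamples without events are redrawn and counted; the
  CI is the percentile interval of apparent − optimism_b.
- **Operating point**: the top 5% of predicted risk is flagged (stable
  patient order breaks ties). PPV/NPV are *not* raw confusion-matrix
  ratios: they are re-pinned by Bayes' rule to a prespecified 2%
  incidence, `PPV = se·π/(se·π + (1−sp)(1−π))`,
  `NPV = sp(1−π)/((1−se)·π + sp(1−π))` — the only construction in which
  a prespecified incidence enters these quantities. When π equals the
  sample event proportion and there is no censoring they reduce to the
  raw ratios (tested).
- **Calibration**: ten equal-count bins of predicted risk; observed risk
  is 1 − Kaplan–Meier survival at 180 days within the bin; percentile CIs
  from 200 within-bin bootstrap resamples.
- **Brier score**: plain mean squared error against the binary 180-day
  outcome; censored-without-event patients score as non-events. No
  inverse-probability-of-censoring weighting, because follow-up in this
  design is nearly complete (median 180 of 180 days); an IPCW variant
  would be the correct generalisation if heavy censoring were introduced.
- **Fairness**: |c_white − c_non-white| against its permutation
  distribution (unknown race excluded, labels permuted holding risks and
  outcomes fixed), with the add-one estimator p = (1+k)/(1+P) so that
  p = 0 is unattainable at P = 100.
- **Model comparison**: patient-level paired bootstrap of the c-index
  difference; percentile CI; two-sided add-one p.

## Synthetic-data generator

The generator emulates the *structure* of a multi-organisation outpatient
EHR extract, not any real dataset: ~20 organisations with normally
distributed baseline hospitalisation log-odds; seven independent
diagnosis flags (rejection-sampled so that everyone has at least one);
Poisson visit schedules thinned by geometric dropout; a stationary
patient-level AR(1) severity path discretised onto the CGI-S and
(inverted, noisier) GAF scales; and an exponential post-window
hospitalisation time with rate
`λ = λ₀·exp(Σβ_k z_k + org effect)`, where the z are the *realized*
window features standardized by fixed config constants and λ₀ solves the
target 180-day baseline risk. Constant hazard within the horizon is the
simplest truth compatible with a proportional-hazards analysis and gives
closed-form per-patient risks for the calibration and recovery oracles.
Every patient draws from a counter-based RNG stream keyed by (seed,
patient index), so datasets are bitwise reproducible and patient i's data
does not depend on how many other patients are generated.

The `preset_reference()` configuration is the package's reference study
condition: 20 organisations (15 derivation / 5 validation), ~57% female,
age 32 ± 19, the reference diagnosis prevalences, median CGI-S severity ≈ 4,
median inverted-GAF severity ≈ 50, ≈1.4% 6-month hospitalisation
incidence among cohort members, near-complete 180-day follow-up, and
per-SD hazard ratios of 1.49 / 1.20 / 1.15 / 1.13 for functional
severity / functional instability / clinical severity / clinical
instability plus diagnosis effects (BD 1.53, SCZ 1.92, ADHD 0.47). The
feature centers and scales are fixed constants calibrated once against
the generator's realized feature distribution (e.g. functional
instability mean ≈ 1.9, SD ≈ 1.75 on this generator — instability
magnitudes depend strongly on the visit-spacing and noise design and are
not tuned to any external table). The GAF anchor is 50 so that the
median inverted severity lands near 50.

What the generator does **not** emulate: diagnosis comorbidity structure,
medication and treatment effects, informative censoring (dropout is
independent of severity), rater effects, or non-constant baseline
hazards. Passing tests therefore demonstrate the *internal* correctness
and calibration of the pipeline under a correctly specified
proportional-hazards world, not performance on real EHR data.

## Test-suite problem sizes

Statistical acceptance checks run at sizes chosen to keep the full suite
in a few minutes of one CPU while leaving each property resolvable:

- coefficient recovery: 100 replicate simulations at n = 5,000 (events
  ≈ 70 each); 95% CI coverage of every generative coefficient must land
  in [90%, 99%] (binomial SD of the coverage estimate ≈ 2.2%). Recovery
  uses a generator configuration without organisation-level frailty so
  the fitted model is correctly specified; organisation effects are
  exercised separately.
- optimism: n = 100 with 20 noise covariates (B = 200) must show mean
  optimism > 0.05; a strong-signal scenario (doubled metric log-hazard
  ratios, 3% baseline risk, n = 10,000, ≈40 events per covariate,
  B = 60) must show optimism < 0.02. At the 1.4%-incidence preset itself
  (≈10 events per covariate) measured optimism is ≈ 0.024 — rare
  outcomes with 14 parameters genuinely overfit, which is the point of
  reporting the corrected index.
- fairness type-I error: 500 replicate null datasets (n = 400, P = 100);
  rejection rate at α = 0.05 must lie in [3%, 7%].
- calibration: outcomes re-simulated from a fitted model's own risks;
  ≥ 8/10 bins on the diagonal within bootstrap CIs (median of 20 seeds).
- pipeline determinism: full run at n = 2,000 executed twice; every
  artifact digest must be byte-identical.

## Known limitations

- One measurement window per patient; no dynamic risk updating.
- The Brier score ignores censoring (see above).
- The org-rate covariate in external validation uses validation-cohort
  outcomes (leakage noted above); an offset or shrunken-rate variant
  would be needed for a deployment-grade external test.
- The adjusted model's organisation covariate assumes the log-odds scale
  is linearly related to log-hazard; frailty models are out of scope.
- Impact arithmetic treats the flagged group's risk as exactly the PPV
  and the intervention as a uniform odds multiplier; it is an
  illustration of targeting efficiency, not a health-economic model.
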