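# Methods

This note documents the models, the synthetic data-generating process,
numerical choices, and known limitations of `statnaive`.

## Landmark framework

A landmark model at age a (40–85, both sexes; 92 models in all) is
fitted to persons under observation at a (entry ≤ a < exit) with no CVD
event and no statin prescription strictly before a. Intervals are
half-open, (a, a + 10]: an event or prescription exactly at the landmark
age counts as after it, which keeps the time-dependent statin split
well-defined (statin time > 0). Follow-up for fitting is
administratively truncated at the 10-year horizon; a minimum positive
follow-up of 1/365.25 years (one day) is enforced because the Weibull
log-likelihood needs time > 0.

The risk set additionally carries the *uncapped* follow-up and the
initiation time within it. These feed the counterfactual transformation
at evaluation time: a statin initiator observed event-free for 12 years
can be counterfactually event-free at 10 years even though shrinking a
horizon-capped 10-year time would fall below the horizon. Fitting uses
capped times; evaluation uses transformed uncapped times.

## Stage 1 — multivariate mixed model and BLUPs

Measurements of SBP, total cholesterol, HDL and smoking within 10 years
before the landmark age are first cleaned with plausibility bounds
(SBP outside [60, 250] mm Hg, TC outside [1.75, 20] mmol/L, HDL outside
[0.3, 3.1] mmol/L set missing, value-wise; bounds closed). The four
factors are modelled jointly:

    y_ijf = β0_f + β1_f (age_ij − a) + u_if + e_ijf,
    u_i ~ N(0, Σ_u)  (4×4, correlated),   e_ijf ~ N(0, σ²_f).

Random structure is correlated random intercepts only — the minimal
structure consistent with sparse primary-care measurement streams; no
random slopes. Smoking is treated as a linear outcome on its 0/1 values
and carried forward as a continuous propensity (clipped to [0, 1], with
a flag when clipping occurs), not re-thresholded.

Estimation is maximum marginal likelihood by EM. Because each
observation belongs to one factor, the per-person information Z'R⁻¹Z is
diagonal, so the E-step reduces to per-person 4×4 solves batched over
the cohort; convergence at relative log-likelihood change < 1e−8 or 500
iterations (typically < 100). Non-convergence is flagged on the fit,
not raised. A factor with no observations keeps a diffuse default
variance, uncorrelated with the rest, and is flagged; its BLUPs reduce
to the population trend. The BLUP is the exact conditional expectation
of the random intercept given the person's observed subset (equivalent
to the dense GLS formula, which the tests verify to machine precision),
so persons with any pattern of missing factors — including all-missing —
get predictions.

The model is fitted on the raw measurement scale; SBP/TC/HDL BLUPs are
standardized on output using sex-specific constants (mean/SD of each
person's first post-entry measurement) computed on the derivation
portion and frozen into the fit, so validation uses identical scaling.
Diabetes and hypertension-treatment status are not modelled here; the
most recent status at the landmark age is carried forward.

## Stage 2 — Weibull proportional hazards with a constrained offset

Follow-up is split at statin initiation; the episode log-likelihood

    ℓ = Σ d·(ln ν + (ν−1) ln stop + η) − e^η (stop^ν − start^ν),
    η = α + x'β + c·statin_on,   c = ln 0.75,

is maximized by BFGS on (ln ν, α, β) with the analytic gradient
(gradient max-norm < 1e−6); ln ν keeps the shape positive without
constraints, and a shape outside [1e−3, 1e3] raises (degenerate time
scale). The offset coefficient c is fixed, never estimated; its value
encodes the trial-meta-analytic 25% hazard reduction and is exposed as a
parameter. Covariance is the inverse observed information (central
differences of the analytic gradient). Ties: initiation at the event
time means no post-initiation exposure and is treated as not initiated
(logged); initiation tied with censoring keeps a one-day post-initiation
episode. The standard model fits the same likelihood on unsplit
follow-up with no statin term.

Predicted 10-year statin-naive risk excludes the offset:
1 − exp(−e^{α+x'β} 10^ν). Setting the multiplier to 1 in both the split
and the counterfactual transform reproduces the standard model's
predictions and the identity t* = t (tested).

### Counterfactual statin-naive times

t* = (t_s^ν + 0.75·(t^ν − t_s^ν))^{1/ν}, applied to event and censoring
times alike; t_s = t when initiation is unobserved. The multiplier 0.75
follows from equating cumulative hazards under the fitted Weibull model:
the untreated process reaches the treated process's accumulated hazard
earlier by exactly the hazard ratio on the t^ν scale. It is a
configuration parameter. ν is taken from the constrained model of the
same landmark age and sex fitted on the derivation portion — the model
whose predictions are being validated.

## Performance measures

* Calibration: tenths of predicted risk vs the product-limit observed
  risk at the horizon; the slope is the coefficient of the centred
  log-cumulative-hazard prognostic index ln(−ln(1−p)) in a refitted
  one-covariate Weibull model. Constant predictions are a flagged error.
* Brier score: unscaled mean squared error restricted to persons with an
  event within the horizon or ≥ 10 years of (possibly counterfactual)
  follow-up; no censoring weights.
* Harrell's C: concordance over usable pairs, prediction ties 0.5, via
  lifelines; person-resampling bootstrap SE/CI (200 reps, seeded).
* Royston–Sauerbrei D: prognostic index replaced by rankits scaled by
  √(8/π); D is its coefficient in a one-covariate Weibull model;
  R²_D = (D²/σ²)/(D²/σ² + π²/6), σ² = 8/π.
* Categorical NRI at the 10% threshold on the restricted subset, with
  the standard asymptotic component SEs; counterfactual outcomes define
  event status when the new model is the statin-naive one.
* Continuous NRI in the prospective (survival) form: movers by sign of
  p_new − p_old, event probabilities within mover groups by the
  product-limit estimator so censored persons contribute; CIs by
  person-level bootstrap (no tractable closed form for this estimator).
* IDI: difference in discrimination slopes on the restricted subset,
  asymptotic SE.
* Stacked metrics concatenate landmark evaluation sets; the bootstrap
  resamples persons keeping all their landmark rows together.

Impact: NNS = n_total / events-prevented and NNT = n_high /
events-prevented with events-prevented = 0.25 × (product-limit risk
among p ≥ threshold) × n_high; the high-risk set is closed at the
threshold (p ≥ 0.10), matching the reclassification tables' "<10% /
≥10%" categories. Threshold-exceedance proportions are combined across
landmark ages with external age-sex weights; the bundled default is a
synthetic uniform-weight table, since real standard-population weights
are an external input.

## Synthetic cohort

The generator emulates the structure the method assumes:

* Entry ages: max(40, U(30, 85)), giving a realistic mass of persons who
  "turn 40" under observation — without it the age-40 landmark would be
  empty. Administrative censoring at min(13 years, age 95).
* Latent factor trajectories: population mean + linear age trend +
  person random intercept (4×4 covariance); visits are a Poisson process
  (1/person-year) over [entry − 10, exit], each factor observed with
  probability 0.7 per visit; continuous factors add Gaussian residual
  noise, smoking measurements are Bernoulli draws of the latent
  probability.
* Events: Weibull hazard (shape 1.3) on the time-since-entry clock with
  covariates frozen at entry, sex-specific baseline (−5.5/−6.0 log rate
  at 60) and an exponential age gradient (0.06/year) so 10-year risks
  span roughly 1–40% across ages 40–85. Log hazard ratios per SD:
  SBP 0.25, TC 0.25, HDL −0.20; smoking 0.50, diabetes 0.60,
  hypertension treatment 0.30.
* Initiation: yearly Bernoulli while event-free, logit −4.0 at age 60
  and TC 5.5 with slopes 0.05/year and 0.30/(mmol/L) — about 1.8%/year
  at 60, giving initiation fractions comparable to UK primary care.
* Treatment: post-initiation hazard × 0.75, with the event time
  re-inverted from the *same* exponential draw under the piecewise
  cumulative hazard, so treated and untreated potential outcomes are
  exactly coupled and stored as oracle truth along with the closed-form
  statin-naive 10-year risk.

What the generator does **not** emulate, and the corresponding limits of
what green tests show about real data: informative visit processes
(sicker people measured more often), practice-level clustering,
treatment non-adherence, and random slopes in the factor trajectories.
Covariates are frozen at entry, so landmark models at ages far from a
person's entry age are deliberately misspecified in the same way any
fixed-covariate landmark model is. Two visible consequences in
simulation output: (i) crude incidence stratified by *future* initiation
status is dominated by immortal-time dilution (initiators must survive
to initiation) at the modest cholesterol–initiation coupling simulated,
so the raw stratified ordering seen in large EHR cohorts is not
reproduced, although future initiators do carry higher cholesterol and
higher true statin-naive risk; (ii) Brier scores of the statin-naive
model (scored against counterfactual outcomes, which contain more
events) are not level-comparable with the standard model's (scored
against observed outcomes) — discrimination (C, D), IDI and the event
component of the NRI are the between-model comparisons that transfer.

## Problem sizes and determinism

Default analysis runs use cohorts of 10,000–20,000 persons: large enough
that all 92 landmark cells fit (the pipeline flags and skips cells with
fewer than 5 events rather than failing) while a full pipeline completes
in well under a minute. Per-landmark validation cells then hold a few
hundred persons, so per-cell calibration slopes and NRIs are noisy —
orders of magnitude noisier than in a million-person EHR study; the
acceptance quantities are chosen to be stable at these sizes. Every
random quantity (generator, derivation split, bootstraps) is seeded;
rerunning a pipeline with the same seed reproduces output files
byte-for-byte. The derivation/validation split (2:1 by person) uses a
stream decorrelated from the generator's.
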