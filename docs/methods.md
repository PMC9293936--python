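# Methods

## The prediction problem

Patients with severe traumatic brain injury are monitored in the ICU with an
intracranial pressure (ICP) probe and an arterial line (mean arterial
pressure, MAP), stored as 1–5-minute median values.  Cerebral perfusion
pressure is the derived difference CPP = MAP − ICP.  Sustained intracranial
hypertension is the main driver of TBI death, so the running level and trend
of these three signals carry prognostic information that accrues with
monitoring time.  The package estimates the probability of death within 30
days of admission, re-evaluated every 8 hours from hour 24 to hour 120 of
monitoring.

## Preprocessing contract

Time is integer minutes since ICU admission; every window in the package is
half-open `[a, b)` in minutes, which makes aggregation unambiguous and
prevents double counting at boundaries.  Raw second-stamped samples are
rounded half-up to the minute; samples collapsing onto one minute are
reduced to their median, matching how bedside systems store low-frequency
medians.  Physiologically impossible values are removed with *strict*
inequalities — ICP > 100 or < 0 mmHg, MAP > 150 or < 20 mmHg — so boundary
values are retained.  CPP is derived after filtering, only at minutes where
both inputs exist, and is never range-filtered itself.  Missing minutes are
never imputed: a window with no samples yields a missing feature, and a
missing required feature removes the patient from that prediction
time-point.  Eligibility requires age ≥ 16 years and an ICP record whose
span reaches minute 1440; "span" rather than cumulative coverage was chosen
because interrupted low-frequency data are expected and embraced (a
minimum-coverage fraction is available as a knob, default off).

## Feature grammar

Window statistics: mean (`avg`), `min`/`max`, mean of consecutive *signed*
differences (`diff`), population (1/n) variance (`var`), 90th and 10th
percentiles with linear interpolation (`q90`, `q10`), and threshold
fractions — share of ICP samples strictly above 20 mmHg (`ht20`) or
strictly below 10 mmHg (`lt10`), share of MAP samples strictly above
120 mmHg (`ht120`).  Signed differences are the default because `diff` is a
drift measure (over a gap-free window it telescopes to
(last − first)/(n − 1)); an absolute-difference variant sits behind a
config flag.  Consecutive differences are taken between successive
*available* samples regardless of gap length.

Aggregations evaluated at prediction time `t`:

* `begin` — the statistic over `[0 h, 24 h)`;
* `end` — the statistic over `[t − 8 h, t)`;
* `coef` — the ordinary-least-squares slope (per hour) of the statistic's
  value over rolling 4-h windows regressed on window end time, windows
  ending on whole hours from 4 h up to `t`.  The 1-hour stride is a design
  choice: "rolling" implies overlap, the stride is otherwise free, and an
  hourly grid gives ≥ 21 points already for the earliest (24 h) prediction
  while keeping cohort featurization linear in monitoring length.

The default candidate set is {icp, map, cpp} × {avg, diff, var, q90, q10} ×
{begin, end, coef} (45) plus {icp_ht20, icp_lt10, map_ht120} × the three
aggregations (9) — 54 signal features — plus age in decade bins (`agec`,
floor(age/10) clipped to 1–9), 55 candidates total.  `min`/`max` are
implemented as window statistics and can be switched into the grammar
(raising the count to 73) but are excluded by default to match the
54-feature candidate set.  `begin` and `end` statistics are computed
directly on the raw in-window samples (single derived windows), while
`coef` operates on the per-4-h-window statistic sequence.  The grammar is
versioned and hashed; model artifacts embed the hash and predictions refuse
feature tables produced under a different grammar.

## Model

A single pooled logistic regression: one row per (patient, prediction
time) with the patient's 30-day outcome repeated, features standardized to
training mean/SD, and coefficients *constant* across prediction times — all
dynamics enter through the time-varying features.  Pooling is the simplest
training scheme consistent with constant coefficients; a `pooling="last"`
sensitivity mode keeps one row per patient.  A weak L2 ridge (λ = 0.01 on
standardized features, negligible at training sizes) keeps separated fits
finite; the solver is Newton with an exact Hessian, which converges in a
dozen iterations where first-order methods crawl on the strongly collinear
trend features.  Standard errors come from the observed information at the
optimum.

Feature selection is recursive feature elimination: starting from all
candidates, repeatedly refit and drop the feature with the smallest
absolute standardized coefficient (the criterion is a package choice);
every feature-count on the elimination path is scored by mean out-of-fold
AUC under stratified group k-fold cross-validation and the best count wins,
ties going to the smaller subset.  Folds always split **by patient** —
never by row — so a patient's own time-points cannot leak across the
train/test boundary; stratification balances deaths across folds.  Fold
shuffles take an explicit seed recorded in the artifact, and different
seeds may legitimately select different subsets.

Classification at threshold θ ∈ {0.25, 0.50, 0.75} is strict
(`death` iff p > θ), so a tie at exactly the threshold is deterministic
(survival).  Patients whose monitoring ended before a scheduled time, or
with a missing selected feature there, get no prediction at that time.

## Evaluation

Per prediction time, over the patients *with* a prediction there
(the evaluated n is always reported, because attrition changes cohort
composition over time): concordance AUC (ties ½), area under the
precision–recall curve with step-wise interpolation (linear PR
interpolation is optimistic; the uninformative baseline is the death
prevalence), accuracy, and the two error rates.  The default error-rate
convention is clinical: fp rate = fp/(fp + tp), the share of predicted
deaths who survived (1 − precision, the quantity a clinician considering
treatment withdrawal cares about), and fn rate = fn/(fn + tn), the share of
predicted survivors who died.  The textbook fp/(fp + tn), fn/(fn + tp)
convention is available via `convention="classic"`.  Internal validation
averages metric curves across folds; pooling out-of-fold predictions first
is available by evaluating the concatenated tracks.

## Synthetic cohorts

The generator emulates the structure the model assumes, not the physiology:

* **Severity and outcome.**  A latent severity s ~ N(0, 1) drives death
  through logit(p) = a + 1.5·s; `a` is solved by Gauss–Hermite quadrature
  so the population mortality equals the preset target (17 % for the
  training preset).
* **Signals.**  ICP is an exact-discretization Ornstein–Uhlenbeck (AR(1))
  process (mean reversion 0.4/h, stationary SD 4 mmHg) around a patient
  baseline 11 ± 3.5 mmHg shifted by +2.5 mmHg per severity SD, plus 1.5 mmHg
  measurement noise.  Non-survivors with positive severity additionally
  drift upward at 0.08 mmHg/h per severity SD — the *only* time-growing
  signal, deliberately, so "prediction improves with monitoring time" is a
  designed-in, testable property rather than an accident.  MAP is an
  independent OU process around 85 ± 8 mmHg (so CPP inherits the ICP
  signal); an optional coupling ties MAP to severity for sensitivity runs.
* **Ages** come from a piecewise-linear quantile function with knots at
  (16, 28, 46, 59, 92) years — a two-piece construction that hits the
  preset median and IQR exactly in distribution.
* **Monitoring duration** is a latent normal resampled below 24 h and
  censored (mass piled) at the 120-h horizon — the natural model when
  monitoring often outlasts the study window — with latent (μ, σ) solved
  numerically at config time so the *observed* mean/SD equal the preset
  (90.7 h / 31.4 h for the training preset).  Non-survivors are further
  truncated at a simulated death time, 24 h + Exp(168 h); the one-week scale
  reflects a 30-day mortality endpoint in which many deaths occur after
  neuromonitoring ends, and keeps both outcome classes represented at late
  prediction times.  Death truncation can be switched off.
* **Corruption.**  Monitor disconnections are Poisson blocks (1 per 24 h,
  exponential ~30-min length) removed from both signals at once; artifacts
  replace ~1 per 1000 samples with out-of-range spikes that *must* violate
  the four exclusion thresholds, so the preprocessing filter is genuinely
  exercised.  Missingness rates are conservative choices exposed in config,
  not literature-derived.

All randomness flows through one seeded `SeedSequence` hierarchy;
regeneration with the same config is byte-identical.  What the generator
does **not** emulate: mechanistic ICP dynamics (plateau waves,
Monro–Kellie compliance), treatment effects on the signals,
covariate-dependent missingness, or clinical covariates beyond age.
Passing tests on these cohorts therefore demonstrate the pipeline's
statistical machinery — calibration, selection, leak-free validation, the
time-signature mechanism — not clinical performance on real patients.

## Problem sizes and numerics

Cohort-scale checks run at the published training-cohort size (686
patients, minute-resolution sampling, ~6,000 training rows); parameter
recovery uses n = 10,000 single-feature rows and a 2,000-row planted-feature
design (5 informative vs 50 noise).  Percentiles interpolate linearly;
variances are population variances; OLS slopes use the closed form
Σ(x−x̄)(y−ȳ)/Σ(x−x̄)².  Degenerate inputs are defined, not special-cased:
empty windows are missing, single-sample windows make `diff`/`var` missing,
a zero-variance feature is dropped with a warning, a single-class cohort
refuses to fit, and degenerate rate denominators yield missing values with
a log entry.

## Known limitations

The exact published 54-feature list and the original row-assembly scheme
are not verifiable from the available description; the grammar reproduces
the printed count and all 14 features of the published retrained model, and
pooling is the simplest scheme consistent with constant coefficients.  The
error-rate denominators follow the clinical "out of 100 predicted
deaths/survivors" reading; both conventions are computed.  External
validation against real Finnish/Swedish/eICU cohorts is out of reach by
construction — those data are access-restricted — so all quantitative
claims here concern synthetic cohorts.
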