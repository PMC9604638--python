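# Methods

This note documents the models implemented in `pefrisk`, the synthetic
cohort they are exercised on, the defaults that matter, and the numerical
and design choices made where more than one reasonable option existed.

## Exposure estimation

Personal exposure to PM2.5 over an activity is modelled as inhaled dose:
the per-minute exposure for activity *j* is `E_j = Conc × Inh.Rate / 60`,
where `Conc` is the ambient concentration (µg/m³) in the space the activity
occupies and `Inh.Rate` the inhalation rate (m³/min).  The accumulated
daily exposure is `f = Σ_j E_j · T_j` with `T_j` the minutes spent on
activity *j*.  CO2, temperature and relative humidity enter as plain 24 h
means — their physiological role here is ambient conditioning, not dose.

Aggregation windows are half-open 24 h intervals `[AM_{d−1}, AM_d)` between
consecutive morning PEFR measurements (assumed at 07:00), so a day's
features can never contain information at or after its own measurement; the
test suite asserts this by corrupting data after the boundary and checking
rows are unchanged.

Choices:

* **Inhalation rates.**  Published age-by-activity tables are an external
  input.  The shipped default is a single adult resting rate of
  0.012 m³/min, doubled for exertion-class activities (cooking, housework,
  exercise), and fully overridable per activity type via `InhalationTable`.
* **Minute matching.**  Each activity minute takes the concentration of the
  nearest record in the activity's space within a 10-minute gap; at the
  1–2 min sensor cadence nearest-neighbour matching is adequate.  Minutes
  beyond the gap are skipped and counted.
* **Feature vector.**  {PM2.5 dose, CO2 mean, temperature mean, RH mean,
  yesterday's AM and PM PEFR, cooking / road-distance / income levels}.
  The ordinal covariate levels are treated as numeric and standardized.
  A switch (`pm25_as_mean`) replaces the dose with the plain 24 h PM2.5
  mean for sensitivity analyses.
* **Row dropping.**  A daily row requires a valid AM PEFR on both the day
  and the previous day; a missing AM value therefore removes two rows.
  Missing evening values fall back to the same day's AM value rather than
  dropping the row.

## Risk zoning

PEFR_C is the empirical q-quantile (default q = 0.20) of the patient's own
historical morning PEFR values, computed with linear interpolation of order
statistics (`h = (n−1)q + 1`), which makes PEFR_C continuous and monotone
in q.  A day is *risk* iff its morning PEFR is strictly below PEFR_C; a
value exactly at PEFR_C is no-risk.  In the pipeline PEFR_C is estimated
once from the chronologically first 80% of a patient's days (the training
era) and held fixed; re-estimation as data accrue is possible through the
engine's update hooks but is deliberately not a silent default.  At least
10 historical values are required.

## Classification: transfer learning + logistic regression

The population (source) model is a fully connected network — two ReLU
hidden layers of 16 and 8 units, sigmoid output, binary cross-entropy,
Adam, batch 32, early stopping with patience 20 on validation loss —
trained on the pooled labelled days of every cohort patient except the
target, under 10-fold stratified cross-validation; the fold model with the
lowest validation loss is retained.  This is the smallest architecture that
still provides a meaningful last-hidden-layer feature space for the
10²–10³-row problems at hand.

Fine-tuning retrains all layers on the target patient's training data at
0.1× the source learning rate under 5-fold cross-validation, selecting the
best fold model by validation F1 (ties broken by validation loss); a
freeze-first-layer regime is available behind a flag.  SMOTE is applied to
the k−1 training folds only, and early stopping monitors a class-balanced
validation loss on the untouched fold, so model selection sees the
patient's real class distribution without favouring the majority class.
With zero fine-tune epochs the target model is bit-identical to the
source — the identity limit the tests assert exactly.

The 8 last-hidden-layer activations of the target model feed a
logistic-regression head with standard L2 shrinkage (`C = 1`) and balanced
class weights; `p ≥ 0.5` (ties inclusive) outputs the risk class.  Two
numerical findings drove this head design.  First, an unpenalised
8-parameter refit on ~10² patient rows is unstable (quasi-separation in
activation space produces brittle decision thresholds).  Second,
oversampling for the head must not happen in input space: SMOTE
interpolants mapped through the nonlinear network land outside the real
minority's activation region and bias the head against the risk class —
class weighting places the boundary where balanced training would, without
manufacturing synthetic activations.  The stand-alone baseline is a
logistic regression (same L2 default) on the raw standardized features of
the target patient, trained on SMOTE-balanced data.

Protocol: stratified random 80/20 train/test split per patient (a
chronological split — final 20% of days held out — is available via
`split="chronological"` since the data are a time series); standardization,
SMOTE (k = 5 minority neighbours, balancing to
parity) and all model selection happen strictly inside the 80% training
part; the 20% test part is never oversampled.  SMOTE synthesises minority
points as `x + u·(x_nn − x)`, `u ~ U(0,1)`, between a minority point and
one of its k nearest minority neighbours in standardized space.

The network and SMOTE are implemented in numpy / scikit-learn primitives
inside the package; training is fully deterministic given a seed.

## Quantile regression with a variable sliding window

For each τ on the grid {0.01, 0.05, 0.10, …, 0.95, 0.99} a linear
conditional-quantile model is fitted by minimizing the pinball loss, posed
as a linear program and solved with HiGHS; the LP optimum is exact, and on
flat optima (extreme τ, small n) the solver's vertex is returned — the
achieved loss, not the coefficient vector, is the well-defined quantity
there, which is how the tests check it.  Fits at different τ are
independent; quantile crossings are detected and flagged, never repaired.

The sliding window of W days splits 2:1 into training and validation
(default W = 45 → 30/15).  Iteration k trains on days
[s_k, s_k + 30), validates on the next 15, predicts the following
min(m, remaining) days, then slides by m (default 7).  Validation pinball
loss is recorded per window; an optional threshold triggers a refit on the
full window when validation quality is unacceptable — the accept/reject
rule is otherwise left to the caller.  Columns constant within a patient's
series (the static covariates) are dropped before fitting since they are
collinear with the intercept inside any window.

Calibration is `Err_τ = |N_τ/N − τ|` with strict "under" (ties count as
not-under; PEFR is effectively continuous so ties have measure zero).  The
grid-search table reports mean Err_τ in ten τ bands (0.01–0.10 … 0.91–0.99)
by window size, with a band-average column rounded to the display precision
(3 decimals), a raw column-average row (4 decimals), and a grand cell equal
to the mean of the rounded band averages — the convention of summary tables
that average their own printed column.  Per-patient errors are averaged
unweighted across patients.

## Decision engine

Daily procedure: (1) classify tomorrow's risk from today's features; below
the 0.5 threshold the report says noRisk and the quantile model is not
consulted; (2–3) otherwise predict PEFR(τ_c) at the critical quantile
τ_c = 0.2 (aligned with the zoning cutoff); (4) alert iff PEFR(τ_c) fell
below its previous value by more than θ.  Defaults: θ = 5% of the patient's
median PEFR (both τ_c and θ are mandatory-visible configuration).  "Previous
value" means the most recent day on which the quantile model was consulted,
since no PEFR(τ_c) exists on noRisk days.  Update hooks receive every step
outcome and may adjust τ_c or PEFR_C; they are no-ops by default because no
principled update rule presents itself, and inventing one silently would be
worse than none.

## Synthetic cohort generator

The generator emulates the structure of a 19-patient adult asthma cohort
observed over one winter: per-patient diary lengths drawn from a Beta law
scaled to 118–212 days with mean 154; twice-daily PEFR; 30-minute activity
diaries tiling each day across three home spaces (bedroom, living room,
kitchen); and sensor streams at a 60 s or 120 s cadence (default 120 s —
deployed units log at either rate).

* **Pollutant dynamics.**  Each variable follows a discretised
  Ornstein–Uhlenbeck (AR(1)) process around a slowly drifting daily base
  level (itself AR(1) across days), plus a diurnal sinusoid, space offsets,
  and activity-linked pulses: cooking injects PM2.5 pulses in the kitchen
  (spilling attenuated into other rooms) and occupancy forces CO2 upward
  with a ~40 min relaxation.  Base levels are calibrated so the cohort
  medians of daily means sit near the published cohort summary
  (PM2.5 ≈ 36 µg/m³, CO2 ≈ 880 ppm, 22.4 °C, 33% RH).
* **PEFR.**  Morning PEFR is `baseline_i + 0.3·(PEFR_{d−1} − baseline_i) +
  effect(X_{d−1}) + ε`, ε ~ N(0, 20 L/min), with patient baselines
  N(373.3, 50) L/min and yesterday's exposures computed from the same
  sensor streams the patient emits, so the downstream feature builder
  recovers the generating signal.  Default linear effects: −1.5 L/min per
  PM2.5 dose unit, −0.05 per ppm CO2, +1.5 per °C, −0.5 per %RH.
* **Shared nonlinear structure.**  Two cohort-shared nonlinearities ride on
  the linear effects: a convex dose-response (the PM2.5 slope doubles above
  the reference dose, mean-centered so the median PEFR is unshifted) and a
  humid-air potentiation of the particulate effect (the PM2.5 effect is
  scaled by `1 + 4·(RH − ref)/5`, i.e. a PM2.5 × RH interaction).  This is
  the population-level structure that makes transfer learning meaningful:
  it is shared by all patients, learnable from ~2 700 pooled days, and not
  representable by a logistic regression that is linear in the raw features
  of a single patient's ~120 training days.  With a purely linear
  generating model the stand-alone logistic baseline is already
  near-optimal and no feature-learning pipeline can systematically beat
  it — an important caveat when reading the synthetic comparison.  Both
  terms are configurable (`pm25_hinge_factor = 1`, `pm25_rh_synergy = 0`
  restore linearity); the response stays monotone in each exposure, which
  the null-signal and sign-recovery tests rely on.
* **What the generator does not emulate.**  Outdoor pollution coupling,
  weather, seasonality beyond one sinusoid, building physics, measurement
  error in diaries, device dropouts beyond uniform missingness, and any
  within-day PEFR dynamics.  Passing tests on this cohort show the
  pipeline's mechanics and its qualitative behaviour (transfer gain
  direction, calibration U-shape), not clinical performance on real
  patients.

## Problem sizes used in tests and the acceptance script

Quantile calibration on the well-specified series uses 600 days (≥ 500
pooled out-of-window test days); the calibration U-shape averages 12
patient series (3 seeds × 4 patients); the classifier comparison averages
20–30 patient evaluations (10 cohort seeds × 2–3 rotating target patients),
each with its own leave-one-patient-out source model under the full
10-fold / 5-fold protocol.  These sizes keep a complete run in the minutes
range on one CPU.  The sensitivity gain is a seed-average with
substantial block-to-block sampling noise (per-patient sensitivity on
~30-day test sets is quantised in steps of ~1/6), so estimates from a few
dozen evaluations can occasionally dip negative even though the average
across hundreds of evaluations is positive; the specificity and ROC AUC
gains are far more stable.

## Known limitations

* Per-patient sensitivity/specificity on ~30-day test sets is coarse
  (quantised in steps of ~1/6), so single-patient comparisons between
  pipelines are uninformative; only cohort/seed averages are meaningful.
* The quantile models share the classifier's feature set; no attempt is
  made to select QR-specific predictors.
* Extreme quantiles (τ ≤ 0.1, τ ≥ 0.9) fitted on 30-day windows are
  intrinsically unstable — visible as the U-shape in band-averaged Err_τ.
* The engine's alert logic compares successive PEFR(τ_c) predictions, not
  observed values; its clinical utility depends entirely on upstream model
  quality.
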