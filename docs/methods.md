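# Methods

## Problem

In type 1 diabetes, the postprandial glycaemic response (PPGR) — how much a
meal raises blood glucose over the following two hours — varies strongly
between individuals given the same carbohydrate load, which makes fixed
carbohydrate-counting rules for insulin dosing unreliable. This package
implements a personalised PPGR modelling pipeline for small continuous
glucose monitoring (CGM) studies: gap imputation for the CGM traces, meal
usability filtering, per-meal response statistics, gradient-boosted
prediction from 38 clinical/dietary/CGM features, and SHAP attribution of
the fitted model. Because clinical datasets of this kind are private, the
package also includes a first-class synthetic cohort generator with known
ground truth, on which every stage is exercised and tested.

## CGM data model

Traces live on a regular 5-minute grid (the cadence of current
subcutaneous sensors). Raw readings snap to a grid anchored at each
patient's first reading rounded down to a 5-minute boundary; a timestamp
exactly halfway between slots rounds up. Canonical unit is mg/dL
(mmol/L × 18.016 at the load boundary only). Readings outside
[20, 600] mg/dL are rejected rather than clamped — clamping would
fabricate sensor data. All windows are half-open `[t0+a, t0+b)` in
minutes; two readings mapping to one slot is a load error, never a silent
overwrite.

## Response statistics

For a meal at time `t0` with grid values `y_0..y_n` over `(t0, t0+120]`
(`n = 24`, `h_i = 5` min):

* baseline `y0` = median of the 30-minute window anchored at the meal.
  "The first 30 minutes of the meal" is genuinely ambiguous between the
  pre- and post-meal half-hour; the default is the pre-meal window
  `[t0-30, t0)`, because a baseline should predate the meal's effect,
  with `baseline_window="post"` available for sensitivity analysis. A
  median needs at least 3 values or the meal is rejected
  (`INSUFFICIENT_BASELINE`).
* `PPGR = Σ_{i=1..n} (h_i/2) · (y_{i-1} + y_i − 2·y0) / y0` — the signed
  trapezoidal incremental AUC of the relative excursion. Negative
  increments are retained (the formula as stated); `clip_negative=True`
  gives the classical iAUC variant that floors each trapezoid at zero.
* `Glu_max = max_{i=1..n} y_i − y0`, possibly negative; chosen for its
  robustness to meal-logging time errors.

Both statistics require a complete postprandial window, so imputation runs
before response computation. The implementation is verified against an
independent brute-force trapezoid oracle to 1e-9, and against closed-form
shift/scale identities (PPGR is scale-invariant; Glu_max is
shift-invariant and scale-equivariant).

## Meal filters

Three rules, order-independent and strict at the boundary:
another meal of the same patient strictly within 90 minutes
(`ADJACENT_WITHIN_90MIN` — mealtime insulin returns to basal in roughly
90–120 min, so closer meals confound each other; both members of a close
pair are dropped by default since the contamination is bidirectional, and
`adjacent_policy="later"` keeps the earlier meal); any required field
absent (`INCOMPLETE`; the 4-hour basal dose is excluded from the required
set because it is reconstructable from a patient's basal schedule);
carbohydrates strictly over 200 g (`CARBS_OVER_200G`, implausible
single-meal intake treated as a logging outlier; exactly 200 g is kept).
Every record receives exactly one verdict row (full audit trail).

## Imputation

CGM traces are stacked as a patient-day × 288 matrix so the networks can
exploit time-of-day correlation, min-max normalised to [0, 1] over
observed entries. GAIN trains a generator
`X̄ = G(X̃, M, (1−M)⊙Z)` and a per-entry discriminator that receives the
completed matrix plus a hint (the true mask with entries blanked to 0.5 at
rate `1 − hint_rate`); the discriminator minimises cross-entropy toward
the mask, the generator maximises the discriminator's error on missing
entries plus `α_rec` times the reconstruction error on observed entries.
Both networks are two-hidden-layer fully connected numpy MLPs (width =
288) with hand-written backpropagation and Adam — at this size a deep
learning framework adds nothing, and training is exactly reproducible
under a seed. Defaults: `hint_rate 0.9`, `α_rec 100`, noise
`Z ~ U[0, 0.01)`, batch 64, learning rate 1e-3, 150 epochs (sized for a
~180 × 288 cohort matrix; more epochs help little on data this small).
The final imputation is `M⊙X̃ + (1−M)⊙X̄`, de-normalised and clipped to
the sensor range; observed entries pass through bit-exactly.

Baselines: KNN (mean of the k=5 nearest rows under nan-Euclidean
distance, i.e. mutually missing columns ignored and rescaled by shared
count; backed by scikit-learn's `KNNImputer`), per-series linear
interpolation in time with nearest-value edge extension, and column mean.
The masking benchmark removes nothing real: it takes the *complete*
traces, hides 10% of cells uniformly at random, hands the identical
masked matrix to every method, and scores
`MAE = Σ_masked |x̂ − x| / n_masked` in mg/dL. Observed-entry
preservation is asserted for every method inside the benchmark.

On the default synthetic cohort GAIN clearly beats column-mean and KNN
imputation; plain linear interpolation wins under this particular
protocol because uniformly random single-cell masking almost always
leaves both immediate neighbours of a hole observed — the regime linear
interpolation is optimal for. Real CGM dropouts are bursty, which is why
the generator's gap model uses geometric run lengths (mean 4 slots) and
why GAIN is the pipeline default.

## Synthetic cohort generator

The generator emulates a 13-patient, 14-day CGM study with three logged
meals a day and is the test bed for everything downstream. What it
reproduces: cohort-level demographics (age ~ N(38, 10) clipped adult,
BMI ~ N(21, 2.1), ~10:3 female:male), 19 blood analytes drawn normal
around published cohort means/SDs (e.g. HbA1c 8.08 ± 2.26%, serum
chloride 105.57 ± 1.52 mmol/L) and clipped positive, anthropometrics
consistent with BMI by construction, per-meal macronutrients around
53.6 ± 11.5 g carbohydrate / 19.1 ± 5.9 g fat / 20.7 ± 4.4 g protein,
calories by the 4/4/9 rule, bolus = carbs / patient carb-ratio
(ratio ~ N(10, 2) g/unit) plus noise, and a per-patient 4-h basal
constant.

Glucose traces are built additively: patient baseline
(~N(140, 20) mg/dL) + per-meal excursions + AR(1) sensor noise
(innovation SD 8 mg/dL, coefficient 0.8), clipped to [40, 400]. Each
meal adds `A · k(t − t_meal)` with the unit-peak kernel
`k(t) = (t/τ)·exp(1 − t/τ)`, τ = 45 min, truncated at 180 min —
matching the typical time-to-peak and decay of a mixed-meal excursion.
The amplitude is a transparent linear model,

    A = s_p · (1.2·carbs + 0.5·protein + 0.3·fat − 4.0·bolus)
        + 0.8·(G_pre − 110) + ε,   ε ~ N(0, 12)

with `s_p = 1 + 0.25·(HbA1c_p − 8.08)/2.26` a per-patient sensitivity
tied to HbA1c and `G_pre` the realised trace value just before the meal.
The coefficients are chosen so carbohydrates alone explain a minority of
amplitude variance (net carb effect is damped because bolus tracks
carbs), the 3-feature standard-of-care variant adds real signal
(pre-meal glucose, bolus), and only the full 38-feature model can see
the HbA1c-linked sensitivity — so the ordering
full > insulin_baseline > carb_only holds by construction, not by
accident of one seed.

A consequence worth knowing: the *designed dominant driver differs by
target*. The HbA1c multiplier scales the whole meal term and survives
the PPGR's division by y0, so it dominates PPGR attribution; the
pre-meal-glucose effect largely cancels there (net sensitivity
≈ β_baseline − A/y0 per mg/dL) but is undamped for Glu_max, where
glucose at meal initiation stays a top feature. `GroundTruth`
records the per-meal noiseless amplitudes and the per-target dominant
feature for tests only — the modelling stages never see it.

What the generator does *not* emulate: insulin–glucose ODE dynamics,
circadian insulin-sensitivity variation, exercise, stress, microbiome
effects, sensor drift/compression artifacts, or logging errors in meal
times. Passing tests therefore demonstrate that the pipeline recovers
structure that is present and correctly ranks information-richer models
— not that these effect sizes or correlations transfer to any real
cohort.

Missingness is injected in geometric-length runs (bursty, like real
dropouts) targeting a 10% missing fraction by default; the masked true
values are retained in a hidden table for evaluation only.

## Prediction models

Targets are PPGR and Glu_max; features are the 38-entry vector (6 meal,
19 blood, 5 anthropometric, 2 survey, 4 CGM-derived, 2 insulin). Trend
features use present-minus-past (`y(t0) − y(t0−δ)`, δ ∈ {30, 60, 120}
min, positive = rising); the literal past-minus-present reading differs
only by sign and is available via `trend_sign="literal"`. Ratio features
with zero denominators become NaN and flow through LightGBM's native
missing handling rather than an arbitrary sentinel.

Meals are split 60/40 at random (per-meal; `grouped=True` offers the
patient-disjoint, leakage-free alternative) once, shared by all six
variant × target fits. Each fit tunes seven LightGBM hyperparameters —
learning_rate (log-uniform [1e-3, 0.3]), n_estimators [50, 1000],
max_depth [2, 12], colsample_bytree [0.4, 1], min_child_samples [1, 50],
num_leaves [8, 256], subsample [0.4, 1] — by a Tree-structured Parzen
Estimator with a 25% random-search share (10 random startup trials,
good/bad split at the 0.25 loss quantile, factorised 1-D Gaussian KDEs,
24 candidates per dimension scored by the density ratio). The tuning
objective is 5-fold cross-validated squared error on a seeded 80%
subsample of the training meals; default budget 25 trials, sized to the
~550-meal synthetic cohort. Evaluation is the Pearson correlation
between predicted and observed validation responses, with explained
variance reported as r². LightGBM runs single-threaded and
deterministic under the seed; models round-trip through LightGBM's text
format to identical predictions.

## Attribution

SHAP values come from LightGBM's built-in exact TreeSHAP
(`pred_contrib=True`) — the same polynomial-time algorithm the dedicated
SHAP tooling dispatches to for tree ensembles — so the additivity
identity (base value + per-feature contributions = prediction) holds to
float precision and is asserted, not assumed. Ranking is by mean |SHAP|
with ties broken in canonical feature order; the feature–response
correlation heat map is exported as a plain CSV matrix (NaN for
zero-variance columns rather than a fabricated 0).

## Numerical and degenerate-input choices

* 2.5-minute rounding ties go up (half-up), both for meal times and CGM
  snapping.
* GAIN aborts on non-finite loss with the epoch in the message.
* A patient-day with no observed CGM value is dropped from the
  imputation matrix with a warning and filled by within-series linear
  interpolation as a last resort.
* Zero-variance predictions or targets make the Pearson r undefined;
  the evaluation flags this (`degenerate: true`) instead of propagating
  NaN.
* Tuning on a zero-variance target is an error; fitting one with a
  fixed configuration is allowed (constant prediction).
* All randomness flows from explicit integer seeds; the pipeline derives
  one recorded sub-seed per stage from the master seed, so stages can be
  rerun in isolation and two runs of the same configuration produce
  identical manifests.

## Known limitations

The generator's linearity makes the variant ordering easier to detect
than in clinical data, where the full model's advantage is smaller and
noisier. Per-meal random splitting lets the model use patient identity
implicitly (all analytes are patient-constant); the grouped split is the
honest generalisation estimate and gives lower correlations. The
masking benchmark's uniform protocol favours interpolation; a bursty
masking benchmark can be run by masking with the generator's gap model
instead. PPGR values are reported in minutes of relative excursion and
depend on the baseline-window convention; comparisons across studies
need the same convention.
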