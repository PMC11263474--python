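# ppgrlab

Personalised **postprandial glycaemic response (PPGR)** modelling for
continuous-glucose-monitoring (CGM) studies in type 1 diabetes.

Given per-patient CGM traces (5-minute grid, mg/dL), meal logs
(macronutrients, calories, insulin doses) and clinical profiles
(anthropometrics plus 19 blood analytes), the package:

1. **imputes CGM gaps** with a GAIN (Generative Adversarial Imputation
   Network) imputer, benchmarked against KNN, linear-interpolation and
   column-mean baselines under a shared-mask masked-MAE protocol;
2. **filters meals** by three usability rules (another meal strictly within
   90 min; incomplete record; carbohydrates > 200 g), with a per-record
   audit trail;
3. **computes per-meal response statistics**: baseline
   `y0` (median of the 30-min window at the meal), the signed trapezoidal
   incremental AUC

   `PPGR = Σᵢ (hᵢ/2)·(yᵢ₋₁ + yᵢ − 2y0)/y0`,  `hᵢ = 5 min`,

   over the 2-hour postprandial window, and `Glu_max = maxᵢ yᵢ − y0`;
4. **predicts PPGR and Glu_max** with LightGBM tuned by a Tree-structured
   Parzen Estimator + random search over 7 hyperparameters, in three
   variants — carbohydrates only, the 3-feature insulin standard-of-care
   baseline (carbs, bolus, glucose at meal), and the full 38-feature model
   — evaluated by the validation Pearson r on one shared 60/40 meal split;
5. **explains the model** with exact TreeSHAP attributions (additivity
   asserted to 1e-6) and a feature–response correlation matrix.

Because clinical datasets of this kind are private, the package ships a
seeded **synthetic cohort generator** (13 patients × 14 days by default)
with known ground truth — meal-driven excursions that depend on
carbohydrates, insulin, pre-meal glucose and an HbA1c-linked per-patient
sensitivity — on which the whole pipeline is exercised and tested. See
`docs/methods.md` for the model and its assumptions.

## Worked example

```python
import numpy as np
from ppgrlab import (CohortConfig, simulate_cohort, apply_filters,
                     build_response_table, build_feature_table, run_comparison)
from ppgrlab.impute import impute_series

cohort = simulate_cohort(CohortConfig(seed=0))          # 13 patients x 14 days
imputed = impute_series(cohort.cgm, method="gain", gain_epochs=150, seed=0)
kept, verdicts, summary = apply_filters(cohort.meals)
masks = {pid: ~np.isnan(s.values) for pid, s in cohort.cgm.items()}
responses, _ = build_response_table(kept, imputed, masks)
table, _ = build_feature_table(kept, cohort.profiles, imputed, responses)
results = run_comparison(table, seed=0, n_trials=25)
for (target, variant), res in results.items():
    print(target, variant, round(res.evaluation["pearson_r"], 3))
```

prints

```
ppgr carb_only 0.226
ppgr insulin_baseline 0.399
ppgr full 0.671
glu_max carb_only 0.204
glu_max insulin_baseline 0.486
glu_max full 0.658
```

i.e. on the synthetic cohort the full 38-feature model predicts the
validation responses far better (r ≈ 0.66–0.67) than the standard-of-care
baseline (r ≈ 0.40–0.49), which in turn beats carbohydrate counting alone
(r ≈ 0.20–0.23) — the ordering the richer clinical context is designed to
produce. `res.evaluation["explained_variance"]` reports r².

The same pipeline is available from the shell:

```bash
ppgr simulate --n-patients 13 --days 14 --seed 0 --out run/
ppgr impute --method gain --in run/ --out run/
ppgr filter --in run/ --out run/
ppgr metrics --in run/ --out run/responses.csv
ppgr features --in run/ --responses run/responses.csv --out run/features.csv
ppgr compare --features run/features.csv --seed 0 --out run/comparison.json
ppgr explain --features run/features.csv --out run/attribution/
ppgr run --seed 0 --out run/        # everything, with a manifest
```

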