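"""Per-meal feature assembly: the 38-feature model input vector.

Categories and counts:

* meal content (6): calories, protein, fat, carbohydrates, carb/fat
  ratio, carb/protein ratio;
* blood tests (19): HbA1c, creatinine, sodium, potassium, serum
  chloride, calcium, total bilirubin, uric acid, ALT, AST, ALP, total
  protein, albumin, cholesterol, triglycerides, HDL, LDL, TSH, fasting
  C-peptide;
* anthropometrics (5): weight, height, waist, hips, BMI;
* survey (2): age, gender (female=0, male=1);
* CGM-derived (4): glucose at meal initiation and the trends over the
  30/60/120 minutes before the meal;
* insulin (2): bolus dose before the meal, 4-hour basal insulin.

Trend convention: trend_d = y(t0) - y(t0 - d), so positive means
glucose was rising into the meal.  Zero-denominator macronutrient
ratios are recorded as NaN — LightGBM's native missing-value handling
— rather than an arbitrary large constant.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cgm import CgmSeries
from .cohort import ANALYTE_NAMES

MEAL_FEATURES = ["calories", "protein", "fat", "carbs", "carb_fat_ratio", "carb_protein_ratio"]
ANTHRO_FEATURES = ["weight", "height", "waist", "hips", "bmi"]
SURVEY_FEATURES = ["age", "gender"]
CGM_FEATURES = ["glucose_at_meal", "trend_30", "trend_60", "trend_120"]
INSULIN_FEATURES = ["bolus_insulin", "basal_insulin_4h"]

#: canonical order of the 38 model inputs
FEATURE_NAMES: list[str] = (
    MEAL_FEATURES + ANALYTE_NAMES + ANTHRO_FEATURES + SURVEY_FEATURES
    + CGM_FEATURES + INSULIN_FEATURES
)
assert len(FEATURE_NAMES) == 38

TREND_DELTAS = (30, 60, 120)

VARIANTS: dict[str, list[str]] = {
    "carb_only": ["carbs"],
    "insulin_baseline": ["carbs", "bolus_insulin", "glucose_at_meal"],
    "full": FEATURE_NAMES,
}


def glucose_at_meal(series: CgmSeries, t0: pd.Timestamp) -> float:
    """Imputed-grid glucose value at the meal time."""
    slot = series.slot_of(t0)
    if not 0 <= slot < len(series.values):
        raise ValueError(f"meal time {t0} outside the recorded CGM span")
    v = series.values[slot]
    if np.isnan(v):
        raise ValueError(f"glucose missing at {t0}; impute first")
    return float(v)


def glucose_trend(series: CgmSeries, t0: pd.Timestamp, delta: int) -> float:
    """y(t0) - y(t0 - delta); positive = glucose rising into the meal."""
    if delta not in TREND_DELTAS:
        raise ValueError(f"delta must be one of {TREND_DELTAS}, got {delta}")
    now = glucose_at_meal(series, t0)
    then_slot = series.slot_of(t0 - pd.Timedelta(minutes=delta))
    if then_slot < 0:
        raise ValueError(f"t0 - {delta} min precedes the recorded CGM span")
    then = series.values[then_slot]
    if np.isnan(then):
        raise ValueError(f"glucose missing at t0 - {delta} min; impute first")
    return float(now - then)


def macro_ratios(carbs: float, fat: float, protein: float) -> tuple[float, float]:
    """(carb/fat, carb/protein); zero denominators give NaN."""
    cf = carbs / fat if fat > 0 else np.nan
    cp = carbs / protein if protein > 0 else np.nan
    return cf, cp


def assemble_features(
    meal: pd.Series, profile: pd.Series, series: CgmSeries, trend_sign: str = "rising"
) -> pd.Series:
    """Build one 38-entry feature row for a meal.

    ``trend_sign='literal'`` flips the trend features to past-minus-
    present; the default keeps positive = rising.  Raises if the
    profile lacks an analyte or a CGM-derived feature is unavailable.
    """
    if trend_sign not in ("rising", "literal"):
        raise ValueError(f"trend_sign must be 'rising' or 'literal', got {trend_sign!r}")
    for name in ANALYTE_NAMES:
        if name not in profile or pd.isna(profile[name]):
            raise ValueError(f"profile of {profile.get('patient_id')} missing analyte {name!r}")
    t0 = meal["meal_time"]
    cf, cp = macro_ratios(meal["carbs_g"], meal["fat_g"], meal["protein_g"])
    sign = -1.0 if trend_sign == "literal" else 1.0
    row = {
        "calories": meal["calories_kcal"],
        "protein": meal["protein_g"],
        "fat": meal["fat_g"],
        "carbs": meal["carbs_g"],
        "carb_fat_ratio": cf,
        "carb_protein_ratio": cp,
        **{name: profile[name] for name in ANALYTE_NAMES},
        "weight": profile["weight"],
        "height": profile["height"],
        "waist": profile["waist"],
        "hips": profile["hips"],
        "bmi": profile["bmi"],
        "age": profile["age"],
        "gender": 0.0 if profile["gender"] == "female" else 1.0,
        "glucose_at_meal": glucose_at_meal(series, t0),
        **{
            f"trend_{d}": sign * glucose_trend(series, t0, d) for d in TREND_DELTAS
        },
        "bolus_insulin": meal["bolus_u"],
        "basal_insulin_4h": meal["basal_4h_u"],
    }
    return pd.Series(row, index=FEATURE_NAMES, dtype=float)


def variant_subset(features: pd.DataFrame, variant: str) -> pd.DataFrame:
    """Restrict a feature table to one model variant's columns."""
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected one of {sorted(VARIANTS)}")
    return features[VARIANTS[variant]]


def build_feature_table(
    meals: pd.DataFrame,
    profiles: pd.DataFrame,
    imputed: dict[str, CgmSeries],
    responses: pd.DataFrame,
    trend_sign: str = "rising",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assemble the modelling table: 38 features + identifiers + targets.

    Only meals present in ``responses`` (i.e. with computable PPGR and
    Glu_max) are included; meals whose CGM-derived features cannot be
    computed are logged in the returned rejection table.
    """
    prof_idx = profiles.set_index("patient_id")
    resp_idx = responses.set_index(["patient_id", "meal_time"])
    rows, meta, rejects = [], [], []
    for _, meal in meals.iterrows():
        pid, t0 = str(meal["patient_id"]), meal["meal_time"]
        if (pid, t0) not in resp_idx.index:
            continue
        try:
            row = assemble_features(meal, prof_idx.loc[pid], imputed[pid], trend_sign)
        except (ValueError, KeyError) as e:
            rejects.append((pid, t0, str(e)))
            continue
        rows.append(row)
        resp = resp_idx.loc[(pid, t0)]
        meta.append((pid, t0, resp["ppgr"], resp["glu_max"]))
    feats = pd.DataFrame(rows).reset_index(drop=True)
    meta_df = pd.DataFrame(meta, columns=["patient_id", "meal_time", "ppgr", "glu_max"])
    table = pd.concat([meta_df, feats], axis=1)
    reject_table = pd.DataFrame(rejects, columns=["patient_id", "meal_time", "reason"])
    return table, reject_table
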