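"""Seeded synthetic cohort emulating a small type-1-diabetes CGM study.

Real hospital CGM/meal/clinical data of this kind are private, so every
downstream stage (imputation, filtering, response metrics, modelling,
attribution) is exercised on a simulated cohort with known ground truth.

What is emulated
----------------
* a 13-patient cohort wearing CGM for two weeks, three logged meals/day;
* patient profiles: age ~ N(38, 10), BMI ~ N(21, 2.1), ~10:3
  female:male, and 19 blood analytes drawn around published
  cohort-level means/SDs (see :data:`ANALYTE_STATS`);
* per-meal macronutrients around the cohort means (carbohydrate
  53.6 ± 11.5 g, fat 19.1 ± 5.9 g, protein 20.7 ± 4.4 g), calories by
  the 4/4/9 kcal-per-gram rule, bolus insulin dosed from each patient's
  carbohydrate ratio;
* meal-driven glucose excursions: each meal adds an amplitude-scaled
  gamma-like kernel ``k(t) = (t/tau) * exp(1 - t/tau)`` (peak 1 at
  ``t = tau`` = 45 min, truncated at 180 min) on top of the patient's
  baseline, plus AR(1) sensor noise;
* MCAR-style CGM dropouts in bursty (geometric-length) runs.

The excursion amplitude is a transparent linear model of carbohydrates,
protein, fat, bolus insulin and pre-meal glucose, modulated by a
per-patient sensitivity tied to HbA1c — so which features *should*
matter downstream is known by construction and recorded in
:class:`GroundTruth` (test-only; never consumed by the modelling
stages).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterable

import numpy as np
import pandas as pd

from .cgm import GRID_MINUTES, CgmSeries

#: blood analyte reference (name, unit, cohort mean, cohort SD)
ANALYTE_STATS: list[tuple[str, str, float, float]] = [
    ("hba1c", "%", 8.08, 2.26),
    ("creatinine", "umol/L", 60.53, 12.64),
    ("sodium", "mmol/L", 137.33, 0.55),
    ("potassium", "mmol/L", 4.19, 0.24),
    ("serum_chloride", "mmol/L", 105.57, 1.52),
    ("calcium", "mmol/L", 2.27, 0.08),
    ("total_bilirubin", "umol/L", 12.71, 3.16),
    ("uric_acid", "umol/L", 296.31, 56.32),
    ("alt", "u/L", 16.86, 6.55),
    ("ast", "u/L", 19.03, 5.74),
    ("alp", "u/L", 74.16, 21.05),
    ("total_protein", "g/L", 71.12, 6.54),
    ("albumin", "g/L", 43.05, 2.57),
    ("cholesterol", "mmol/L", 9.11, 10.79),
    ("triglycerides", "mmol/L", 1.05, 0.54),
    ("hdl", "mmol/L", 1.55, 0.31),
    ("ldl", "mmol/L", 2.74, 1.24),
    ("tsh", "mIU/L", 3.69, 1.89),
    ("fasting_c_peptide", "nmol/L", 0.02, 0.02),
]

ANALYTE_NAMES = [name for name, *_ in ANALYTE_STATS]

#: per-meal macronutrient means/SDs, grams
MACRO_STATS = {"carbs": (53.6, 11.5), "fat": (19.1, 5.9), "protein": (20.7, 4.4)}

#: kcal per gram of carbohydrate/protein and of fat
KCAL_CARB_PROTEIN, KCAL_FAT = 4.0, 9.0

#: excursion kernel time-to-peak, minutes
KERNEL_TAU = 45.0
#: kernel support, minutes (meal effects vanish after this)
KERNEL_SPAN = 180.0


@dataclass
class CohortConfig:
    """Knobs of the simulated study.

    Defaults are the study conditions: 13 patients for 14 days, three
    meals a day, 10% missing CGM data in bursty gaps.  Effect sizes
    (``b_*``) are mg/dL of peak excursion per unit of the covariate;
    defaults are set so that carbohydrates alone explain only a
    minority of amplitude variance while pre-meal glucose and the
    HbA1c-linked sensitivity carry most of the predictable signal.
    """

    n_patients: int = 13
    days_per_patient: int = 14
    seed: int = 0
    # amplitude model, mg/dL peak per unit
    b_carb: float = 1.2  # per gram carbohydrate
    b_protein: float = 0.5  # per gram protein
    b_fat: float = 0.3  # per gram fat
    b_insulin: float = 4.0  # per unit bolus insulin (lowers the peak)
    b_baseline: float = 0.8  # per mg/dL of (pre-meal glucose - 110)
    b_hba1c: float = 0.25  # sensitivity multiplier per SD of HbA1c
    meal_noise_sd: float = 12.0  # mg/dL, per-meal amplitude noise
    noise_sd: float = 8.0  # mg/dL, AR(1) sensor noise innovation scale
    ar_coef: float = 0.8  # AR(1) coefficient of sensor noise
    missing_fraction: float = 0.10
    gap_length_mean: float = 4.0  # slots; geometric run length
    violator_fraction: float = 0.0  # share of extra <90-min meals
    incomplete_fraction: float = 0.0  # share of meals with a field blanked
    highcarb_fraction: float = 0.0  # share of meals pushed over 200 g

    def __post_init__(self) -> None:
        if self.n_patients < 1 or self.days_per_patient < 1:
            raise ValueError("counts must be >= 1")
        if not 0.0 <= self.missing_fraction <= 0.5:
            raise ValueError("missing_fraction must lie in [0, 0.5]")
        for name in ("b_carb", "b_protein", "b_fat", "b_insulin", "b_baseline",
                     "b_hba1c"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"effect size {name} must be finite")


@dataclass
class GroundTruth:
    """Generator-side truth, for tests only — never fed to the models.

    ``amplitudes`` maps (patient_id, meal_time) to the noiseless peak
    excursion; ``dominant_features`` names, per response target, the
    feature designed to carry the most predictable signal downstream.
    The HbA1c-linked sensitivity multiplies the whole meal term, so it
    dominates the ratio-form PPGR, where the pre-meal-glucose effect
    largely cancels against the y0 denominator (net sensitivity
    b_baseline - A/y0 per mg/dL); Glu_max has no such division, so
    glucose at meal initiation stays dominant there.
    """

    amplitudes: dict[tuple[str, pd.Timestamp], float] = field(default_factory=dict)
    carb_ratio: dict[str, float] = field(default_factory=dict)
    baseline_glucose: dict[str, float] = field(default_factory=dict)
    dominant_features: dict[str, str] = field(
        default_factory=lambda: {"ppgr": "hba1c", "glu_max": "glucose_at_meal"}
    )


def _named_rng(seed: int, stream: int) -> np.random.Generator:
    """Independent, reproducible stream per generation stage."""
    return np.random.default_rng(np.random.SeedSequence([seed, stream]))


def generate_profiles(config: CohortConfig) -> pd.DataFrame:
    """Draw patient demographics, anthropometrics and blood analytes.

    Ages are clipped to >= 18 (adult cohort); analytes are drawn
    normal around :data:`ANALYTE_STATS` and clipped positive.  Height,
    weight, waist and hips are drawn so BMI = weight/height^2 holds by
    construction.
    """
    rng = _named_rng(config.seed, 1)
    n = config.n_patients
    pid = [f"P{i:03d}" for i in range(n)]
    # ~10:3 female:male
    gender = np.where(rng.random(n) < 10.0 / 13.0, "female", "male")
    age = np.clip(rng.normal(38.0, 10.0, n), 18.0, None)
    bmi = np.clip(rng.normal(21.0, 2.1, n), 15.0, None)
    height = np.where(
        gender == "female", rng.normal(160.0, 5.5, n), rng.normal(172.0, 6.0, n)
    )
    weight = bmi * (height / 100.0) ** 2
    waist = np.clip(rng.normal(74.0, 7.0, n) + 1.5 * (bmi - 21.0), 50.0, None)
    hips = np.clip(rng.normal(93.0, 6.0, n) + 1.5 * (bmi - 21.0), 60.0, None)
    prof = pd.DataFrame(
        {
            "patient_id": pid,
            "age": np.round(age, 1),
            "gender": gender,
            "height": np.round(height, 1),
            "weight": np.round(weight, 2),
            "waist": np.round(waist, 1),
            "hips": np.round(hips, 1),
            "bmi": np.round(bmi, 2),
        }
    )
    for name, _unit, mean, sd in ANALYTE_STATS:
        prof[name] = np.clip(rng.normal(mean, sd, n), 1e-6, None)
    return prof


#: conventional meal hours (breakfast, lunch, dinner), minutes from midnight
_MEAL_ANCHORS = (7 * 60 + 30, 12 * 60 + 30, 18 * 60 + 30)


def generate_meals(config: CohortConfig, profiles: pd.DataFrame) -> pd.DataFrame:
    """Simulate the meal log: times, macronutrients, insulin.

    Three meals/day at conventional hours with ±40 min jitter (snapped
    to the 5-minute grid), guaranteed >= 90 min apart unless
    ``violator_fraction`` > 0, in which case that share of meals gains
    a deliberate close companion (snack) for filter testing.  Calories
    follow the 4/4/9 rule; bolus = carbs / patient carb-ratio + noise;
    the 4-h basal is a per-patient constant.
    """
    rng = _named_rng(config.seed, 2)
    carb_ratio = dict(
        zip(profiles["patient_id"], np.clip(rng.normal(10.0, 2.0, len(profiles)), 4.0, None))
    )
    basal_4h = dict(
        zip(profiles["patient_id"], np.clip(rng.normal(4.0, 1.0, len(profiles)), 0.5, None))
    )
    day0 = pd.Timestamp("2024-01-01")
    rows = []
    for pid in profiles["patient_id"]:
        for day in range(config.days_per_patient):
            for anchor in _MEAL_ANCHORS:
                jitter = GRID_MINUTES * int(rng.integers(-8, 9))  # ±40 min
                t = day0 + pd.Timedelta(days=day, minutes=anchor + jitter)
                rows.append((pid, t, False))
                if rng.random() < config.violator_fraction:
                    # a snack 30-85 min later, violating the 90-min rule
                    off = GRID_MINUTES * int(rng.integers(6, 18))
                    rows.append((pid, t + pd.Timedelta(minutes=off), False))

    meals = pd.DataFrame(rows, columns=["patient_id", "meal_time", "is_snack"])
    m = len(meals)
    carbs = np.clip(rng.normal(*MACRO_STATS["carbs"], m), 0.0, None)
    fat = np.clip(rng.normal(*MACRO_STATS["fat"], m), 0.0, None)
    protein = np.clip(rng.normal(*MACRO_STATS["protein"], m), 0.0, None)
    if config.highcarb_fraction > 0:
        hi = rng.random(m) < config.highcarb_fraction
        carbs[hi] = rng.uniform(205.0, 300.0, hi.sum())
    meals["carbs_g"] = np.round(carbs, 1)
    meals["protein_g"] = np.round(protein, 1)
    meals["fat_g"] = np.round(fat, 1)
    meals["calories_kcal"] = np.round(
        KCAL_CARB_PROTEIN * (meals["carbs_g"] + meals["protein_g"])
        + KCAL_FAT * meals["fat_g"],
        1,
    )
    ratio = meals["patient_id"].map(carb_ratio).to_numpy()
    meals["bolus_u"] = np.round(
        np.clip(meals["carbs_g"] / ratio + rng.normal(0.0, 0.5, m), 0.0, None), 2
    )
    meals["basal_4h_u"] = np.round(meals["patient_id"].map(basal_4h), 2)
    if config.incomplete_fraction > 0:
        blank = np.flatnonzero(rng.random(m) < config.incomplete_fraction)
        cols = ["protein_g", "fat_g", "bolus_u", "calories_kcal"]
        for i in blank:
            meals.loc[i, cols[int(rng.integers(len(cols)))]] = np.nan
    meals = meals.drop(columns="is_snack")
    meals.attrs["carb_ratio"] = carb_ratio
    meals.attrs["basal_4h"] = basal_4h
    return meals.sort_values(["patient_id", "meal_time"]).reset_index(drop=True)


def excursion_kernel(t_minutes: np.ndarray, tau: float = KERNEL_TAU) -> np.ndarray:
    """Unit-peak meal kernel ``(t/tau) * exp(1 - t/tau)``, truncated.

    Zero before the meal and beyond :data:`KERNEL_SPAN`; maximum
    exactly 1 at ``t = tau``.
    """
    t = np.asarray(t_minutes, dtype=float)
    k = (t / tau) * np.exp(1.0 - t / tau)
    k[(t < 0) | (t > KERNEL_SPAN)] = 0.0
    return k


def generate_cgm(
    config: CohortConfig, profiles: pd.DataFrame, meals: pd.DataFrame
) -> tuple[dict[str, CgmSeries], GroundTruth]:
    """Simulate complete (gap-free) CGM traces driven by the meal log.

    trace(t) = patient baseline + sum over meals A_m * k(t - t_m) + AR(1) noise,
    clipped to [40, 400] mg/dL.  The amplitude of meal m for patient p is

        A_m = s_p * (b_carb*C + b_protein*P + b_fat*F - b_insulin*B)
              + b_baseline * (G_pre - 110) + eps_m

    with s_p = 1 + b_hba1c * (HbA1c_p - mean)/SD the patient's
    HbA1c-linked sensitivity, G_pre the realised trace value just
    before the meal, and eps_m ~ N(0, meal_noise_sd).  Meals are
    applied in time order so G_pre includes earlier meals' tails.
    """
    rng = _named_rng(config.seed, 3)
    hba1c_mean, hba1c_sd = 8.08, 2.26
    n_slots = config.days_per_patient * 24 * 60 // GRID_MINUTES
    day0 = pd.Timestamp("2024-01-01")
    truth = GroundTruth()
    truth.carb_ratio = dict(meals.attrs.get("carb_ratio", {}))
    series: dict[str, CgmSeries] = {}

    prof_idx = profiles.set_index("patient_id")
    for pid in profiles["patient_id"]:
        baseline = float(np.clip(rng.normal(140.0, 20.0), 90.0, 220.0))
        truth.baseline_glucose[pid] = baseline
        s_p = 1.0 + config.b_hba1c * (prof_idx.loc[pid, "hba1c"] - hba1c_mean) / hba1c_sd

        trace = np.full(n_slots, baseline)
        # AR(1) sensor/physiology noise
        if config.noise_sd > 0:
            innov = rng.normal(0.0, config.noise_sd, n_slots)
            noise = np.empty(n_slots)
            noise[0] = innov[0] / np.sqrt(1.0 - config.ar_coef**2)
            for i in range(1, n_slots):
                noise[i] = config.ar_coef * noise[i - 1] + innov[i]
            trace = trace + noise

        t_grid = np.arange(n_slots) * GRID_MINUTES  # minutes from day0
        pm = meals[meals["patient_id"] == pid].sort_values("meal_time")
        for _, meal in pm.iterrows():
            t_meal = (meal["meal_time"] - day0).total_seconds() / 60.0
            slot = int(t_meal // GRID_MINUTES)
            if slot < 1 or slot >= n_slots:
                continue
            g_pre = trace[slot - 1]  # realised value just before the meal
            carbs = 0.0 if pd.isna(meal["carbs_g"]) else meal["carbs_g"]
            protein = 0.0 if pd.isna(meal["protein_g"]) else meal["protein_g"]
            fat = 0.0 if pd.isna(meal["fat_g"]) else meal["fat_g"]
            bolus = 0.0 if pd.isna(meal["bolus_u"]) else meal["bolus_u"]
            amp = s_p * (
                config.b_carb * carbs
                + config.b_protein * protein
                + config.b_fat * fat
                - config.b_insulin * bolus
            ) + config.b_baseline * (g_pre - 110.0)
            if config.meal_noise_sd > 0:
                amp += rng.normal(0.0, config.meal_noise_sd)
            trace = trace + amp * excursion_kernel(t_grid - t_meal)
            truth.amplitudes[(pid, meal["meal_time"])] = float(amp)

        trace = np.clip(trace, 40.0, 400.0)
        series[pid] = CgmSeries(patient_id=str(pid), start=day0, values=trace)
    return series, truth


def inject_missingness(
    series: dict[str, CgmSeries], config: CohortConfig
) -> tuple[dict[str, CgmSeries], dict[str, np.ndarray]]:
    """Mask ~``missing_fraction`` of slots in geometric-length runs.

    Returns the gapped series and, per patient, the hidden true values
    at masked slots (NaN elsewhere) for evaluation only.
    """
    if config.missing_fraction >= 1.0:
        raise ValueError("missing_fraction must be < 1")
    rng = _named_rng(config.seed, 4)
    gapped: dict[str, CgmSeries] = {}
    hidden: dict[str, np.ndarray] = {}
    for pid, s in series.items():
        n = len(s.values)
        mask = np.zeros(n, dtype=bool)
        target = int(round(config.missing_fraction * n))
        guard = 0
        while mask.sum() < target and guard < 10 * n:
            start = int(rng.integers(0, n))
            length = int(rng.geometric(1.0 / config.gap_length_mean))
            mask[start : start + length] = True
            guard += 1
        # trim overshoot from the end of the last run placed
        excess = int(mask.sum()) - target
        if excess > 0:
            idx = np.flatnonzero(mask)
            mask[idx[-excess:]] = False
        vals = s.values.copy()
        truth_vals = np.full(n, np.nan)
        truth_vals[mask] = vals[mask]
        vals[mask] = np.nan
        gapped[pid] = CgmSeries(patient_id=s.patient_id, start=s.start, values=vals)
        hidden[pid] = truth_vals
    return gapped, hidden


@dataclass
class Cohort:
    """Bundle of everything :func:`simulate_cohort` produces."""

    config: CohortConfig
    profiles: pd.DataFrame
    meals: pd.DataFrame
    cgm_complete: dict[str, CgmSeries]
    cgm: dict[str, CgmSeries]
    hidden_truth: dict[str, np.ndarray]
    truth: GroundTruth


def simulate_cohort(config: CohortConfig | None = None) -> Cohort:
    """Run the full generator: profiles -> meals -> CGM -> gaps."""
    config = config or CohortConfig()
    profiles = generate_profiles(config)
    meals = generate_meals(config, profiles)
    cgm_complete, truth = generate_cgm(config, profiles, meals)
    cgm, hidden = inject_missingness(cgm_complete, config)
    return Cohort(config, profiles, meals, cgm_complete, cgm, hidden, truth)
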