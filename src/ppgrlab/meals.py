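"""Meal records, 5-minute time rounding, and the meal filters.

Three rules decide whether a logged meal is usable for response
modelling:

* ``ADJACENT_WITHIN_90MIN`` — another meal of the same patient lies
  strictly within 90 minutes, so its insulin/glucose effects would
  contaminate the postprandial window (mealtime insulin returns to
  basal within roughly 90–120 min);
* ``INCOMPLETE`` — a required field (macronutrients, calories, bolus
  dose, meal time) is absent;
* ``CARBS_OVER_200G`` — carbohydrate content strictly above 200 g, an
  implausibly high single-meal intake treated as a logging outlier.

Boundary semantics are strict and literal: a pair exactly 90 minutes
apart is kept, and exactly 200 g of carbohydrate is kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MEAL_COLUMNS = [
    "patient_id",
    "meal_time",
    "carbs_g",
    "protein_g",
    "fat_g",
    "calories_kcal",
    "bolus_u",
    "basal_4h_u",
]

#: fields whose absence makes a record INCOMPLETE. basal_4h_u is
#: excluded: it can be reconstructed from the patient's basal schedule.
REQUIRED_FIELDS = ["meal_time", "carbs_g", "protein_g", "fat_g", "calories_kcal", "bolus_u"]

ADJACENCY_THRESHOLD_MIN = 90
CARB_CAP_G = 200.0


class FilterReason(str, Enum):
    ADJACENT_WITHIN_90MIN = "ADJACENT_WITHIN_90MIN"
    INCOMPLETE = "INCOMPLETE"
    CARBS_OVER_200G = "CARBS_OVER_200G"


@dataclass
class FilterSummary:
    recorded: int
    kept: int
    by_reason: dict[str, int]

    def to_dict(self) -> dict:
        return {"recorded": self.recorded, "kept": self.kept, "by_reason": self.by_reason}


def round_meal_time(t: pd.Timestamp) -> pd.Timestamp:
    """Round to the nearest 5-minute boundary; 2.5-minute ties round up."""
    t = pd.Timestamp(t)
    secs = (t - t.floor("5min")).total_seconds()
    base = t.floor("5min")
    return base + pd.Timedelta(minutes=5) if secs >= 150 else base


def filter_adjacent(
    meals: pd.DataFrame,
    threshold: int = ADJACENCY_THRESHOLD_MIN,
    policy: str = "both",
) -> pd.Series:
    """Flag meals with another same-patient meal strictly within ``threshold`` minutes.

    ``policy='both'`` flags both members of a close pair (default: the
    contamination is bidirectional); ``policy='later'`` keeps the
    earlier meal and flags only the later one.
    """
    if policy not in ("both", "later"):
        raise ValueError(f"unknown adjacency policy {policy!r}")
    flagged = pd.Series(False, index=meals.index)
    for _, grp in meals.groupby("patient_id"):
        grp = grp.sort_values("meal_time")
        times = grp["meal_time"].to_numpy()
        gaps = np.diff(times).astype("timedelta64[s]").astype(float) / 60.0
        close = gaps < threshold  # strict: exactly `threshold` apart is kept
        idx = grp.index.to_numpy()
        for i, is_close in enumerate(close):
            if is_close:
                flagged[idx[i + 1]] = True
                if policy == "both":
                    flagged[idx[i]] = True
    return flagged


def filter_complete(meals: pd.DataFrame) -> pd.Series:
    """Flag records with any required field absent."""
    return meals[REQUIRED_FIELDS].isna().any(axis=1)


def filter_carbs(meals: pd.DataFrame, cap: float = CARB_CAP_G) -> pd.Series:
    """Flag records with carbohydrates strictly above ``cap`` grams."""
    return meals["carbs_g"] > cap  # NaN compares False; caught by filter_complete


def apply_filters(
    meals: pd.DataFrame,
    threshold: int = ADJACENCY_THRESHOLD_MIN,
    carb_cap: float = CARB_CAP_G,
    adjacent_policy: str = "both",
) -> tuple[pd.DataFrame, pd.DataFrame, FilterSummary]:
    """Run all three rules; return (kept meals, verdict table, summary).

    The verdict table has one row per input record with boolean flag
    columns and a combined ``kept`` column; rule order is irrelevant
    (each rule sees the full input log).
    """
    meals = meals.reset_index(drop=True)
    verdicts = pd.DataFrame(
        {
            "patient_id": meals["patient_id"],
            "meal_time": meals["meal_time"],
            FilterReason.ADJACENT_WITHIN_90MIN.value: filter_adjacent(
                meals, threshold, adjacent_policy
            ),
            FilterReason.INCOMPLETE.value: filter_complete(meals),
            FilterReason.CARBS_OVER_200G.value: filter_carbs(meals, carb_cap),
        }
    )
    reason_cols = [r.value for r in FilterReason]
    verdicts["kept"] = ~verdicts[reason_cols].any(axis=1)
    kept = meals[verdicts["kept"]].reset_index(drop=True)
    summary = FilterSummary(
        recorded=len(meals),
        kept=int(verdicts["kept"].sum()),
        by_reason={c: int(verdicts[c].sum()) for c in reason_cols},
    )
    return kept, verdicts, summary


def load_meals(path: str | Path) -> pd.DataFrame:
    """Read a delimited meal log; meal times are rounded to the grid."""
    df = pd.read_csv(path, parse_dates=["meal_time"])
    missing = set(MEAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"meal file missing columns {sorted(missing)}")
    df["meal_time"] = df["meal_time"].map(round_meal_time)
    df["patient_id"] = df["patient_id"].astype(str)
    return df.sort_values(["patient_id", "meal_time"]).reset_index(drop=True)


def save_meals(meals: pd.DataFrame, path: str | Path) -> None:
    meals.to_csv(path, index=False, columns=[c for c in MEAL_COLUMNS if c in meals.columns])
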