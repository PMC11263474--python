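"""Shared fixtures: the default synthetic cohort and its pipeline products.

Expensive stages (GAIN imputation, the 3x2 model comparison) are
session-scoped so the suite computes them once.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ppgrlab.cohort import CohortConfig, simulate_cohort
from ppgrlab.features import build_feature_table
from ppgrlab.impute import impute_series
from ppgrlab.meals import apply_filters
from ppgrlab.metrics import build_response_table
from ppgrlab.model import run_comparison


@pytest.fixture(scope="session")
def default_cohort():
    """The study-conditions cohort: 13 patients x 14 days, seed 0."""
    return simulate_cohort(CohortConfig(seed=0))


@pytest.fixture(scope="session")
def pipeline_artifacts(default_cohort):
    """Imputed CGM, filtered meals, responses and feature table."""
    c = default_cohort
    imputed = impute_series(c.cgm, method="gain", gain_epochs=150, seed=0)
    kept, verdicts, summary = apply_filters(c.meals)
    masks = {pid: ~np.isnan(s.values) for pid, s in c.cgm.items()}
    responses, resp_rejects = build_response_table(kept, imputed, masks)
    table, feat_rejects = build_feature_table(kept, c.profiles, imputed, responses)
    return {
        "cohort": c,
        "imputed": imputed,
        "kept": kept,
        "verdicts": verdicts,
        "summary": summary,
        "responses": responses,
        "table": table,
    }


@pytest.fixture(scope="session")
def comparison_results(pipeline_artifacts):
    """The 3-variant x 2-target comparison at the default trial budget."""
    return run_comparison(pipeline_artifacts["table"], seed=0, n_trials=25)


@pytest.fixture
def toy_meal_log():
    """Six meals with constructed violations: two 60 min apart, one
    missing protein, one with 250 g carbohydrate, two clean."""
    base = dict(carbs_g=50.0, protein_g=20.0, fat_g=15.0,
                calories_kcal=415.0, bolus_u=5.0, basal_4h_u=4.0)
    rows = [
        {"patient_id": "A", "meal_time": pd.Timestamp("2024-01-01 08:00"), **base},
        {"patient_id": "A", "meal_time": pd.Timestamp("2024-01-01 09:00"), **base},
        {"patient_id": "A", "meal_time": pd.Timestamp("2024-01-01 13:00"),
         **{**base, "protein_g": np.nan}},
        {"patient_id": "A", "meal_time": pd.Timestamp("2024-01-01 19:00"),
         **{**base, "carbs_g": 250.0}},
        {"patient_id": "B", "meal_time": pd.Timestamp("2024-01-01 08:00"), **base},
        {"patient_id": "B", "meal_time": pd.Timestamp("2024-01-01 12:30"), **base},
    ]
    return pd.DataFrame(rows)
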