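"""Model attribution: exact TreeSHAP values and feature correlations.

SHAP (Shapley Additive exPlanations) assigns each feature of each
prediction a contribution such that base value + contributions sum to
the model output exactly.  For tree ensembles the Shapley values are
computed exactly by the TreeSHAP polynomial-time algorithm, exposed
natively by LightGBM (``predict(..., pred_contrib=True)``), which this
module calls; no sampling approximation is involved, so the additivity
identity holds to floating-point precision.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import PPGRRegressor


@dataclass
class AttributionResult:
    """Per-meal, per-feature SHAP values plus the model base value."""

    shap_values: pd.DataFrame  # rows = meals, columns = features
    base_values: np.ndarray  # per-row expected value
    predictions: np.ndarray

    def mean_abs(self) -> pd.Series:
        return self.shap_values.abs().mean(axis=0)


def shap_values(model: PPGRRegressor, X: pd.DataFrame) -> AttributionResult:
    """Exact TreeSHAP attributions for every row of ``X``.

    ``X`` may carry extra columns; the model's training features are
    selected by name, and a missing training feature raises rather
    than silently reordering.
    """
    missing = [f for f in model.feature_names_ if f not in X.columns]
    if missing:
        raise ValueError(f"feature table lacks model features {missing}")
    Xm = X[model.feature_names_]
    contrib = model.booster_.booster_.predict(Xm, pred_contrib=True)
    values = pd.DataFrame(contrib[:, :-1], columns=model.feature_names_)
    base = contrib[:, -1]
    pred = model.predict(Xm)
    return AttributionResult(values, base, np.asarray(pred))


def rank_features(result: AttributionResult, k: int = 20) -> pd.DataFrame:
    """Top-k features by mean |SHAP|, ties broken by canonical order.

    Returns a frame with columns ``feature`` and ``mean_abs_shap``
    sorted descending.
    """
    mean_abs = result.mean_abs()
    if k > len(mean_abs):
        warnings.warn(
            f"k={k} exceeds the {len(mean_abs)} available features; truncating"
        )
        k = len(mean_abs)
    order = sorted(
        range(len(mean_abs)), key=lambda i: (-mean_abs.iloc[i], i)
    )[:k]
    return pd.DataFrame(
        {
            "feature": mean_abs.index[order],
            "mean_abs_shap": mean_abs.iloc[order].to_numpy(),
        }
    )


def feature_correlations(
    features: pd.DataFrame, responses: pd.Series | None = None
) -> pd.DataFrame:
    """Pairwise Pearson correlations among features (and the response).

    Zero-variance columns yield NaN correlations (flagged undefined
    rather than fabricated); the diagonal is 1 for all valid columns.
    """
    frame = features.copy()
    if responses is not None:
        frame = frame.assign(**{responses.name or "response": responses.to_numpy()})
    if len(frame) < 3:
        raise ValueError("need at least 3 meals for correlations")
    return frame.corr(method="pearson")


def beeswarm_table(result: AttributionResult, X: pd.DataFrame) -> pd.DataFrame:
    """Plot-ready long table: one row per (meal, feature) with the SHAP
    value and whether the feature value sits below or above its mean."""
    rows = []
    means = X[result.shap_values.columns].mean()
    for feat in result.shap_values.columns:
        rows.append(
            pd.DataFrame(
                {
                    "feature": feat,
                    "shap_value": result.shap_values[feat],
                    "feature_value": X[feat].to_numpy(),
                    "above_average": (X[feat] > means[feat]).to_numpy(),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)
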