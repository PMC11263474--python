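"""Per-meal glycaemic response statistics: baseline y0, PPGR and Glu_max.

The postprandial glycaemic response (PPGR) is the baseline-normalised
incremental area under the glucose curve over the 2 hours after a meal,
computed by the trapezoidal rule on the 5-minute grid:

    PPGR = sum_{i=1..n} (h_i / 2) * (y_{i-1} + y_i - 2*y0) / y0

with h_i = 5 min, y_0..y_n the grid values from the meal time t0
through t0 + 120 min, and y0 the baseline: the median glucose over a
30-minute window anchored at the meal.  Negative increments are kept
(signed iAUC); a ``clip_negative`` option provides the classical
variant that floors each trapezoid at zero.

Glu_max is the maximum glucose within the 2-hour window minus y0 — a
statistic less sensitive to meal-logging time errors.  Both statistics
require a complete (imputed) postprandial window.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .cgm import GRID_MINUTES, CgmSeries

#: postprandial window length, minutes
POSTPRANDIAL_MIN = 120
#: baseline window length, minutes
BASELINE_MIN = 30
#: minimum observed/imputed values needed for a robust baseline median
MIN_BASELINE_SAMPLES = 3


class InsufficientBaseline(ValueError):
    """Fewer than MIN_BASELINE_SAMPLES values in the baseline window."""


class IncompleteWindow(ValueError):
    """Postprandial window has missing values; impute before computing."""


@dataclass
class ResponseRecord:
    patient_id: str
    meal_time: pd.Timestamp
    y0: float
    ppgr: float
    glu_max: float
    n_samples: int
    coverage: float  # fraction of the 2-h window observed pre-imputation


def baseline_glucose(
    series: CgmSeries, t0: pd.Timestamp, baseline_window: str = "pre"
) -> float:
    """Median glucose over the 30-minute baseline window.

    ``baseline_window='pre'`` uses [t0-30, t0) (the default: baseline
    should predate the meal's effect); ``'post'`` uses [t0, t0+30) for
    sensitivity analysis.  Requires at least 3 non-missing values.
    """
    if baseline_window == "pre":
        vals = series.window(t0, -BASELINE_MIN, 0)
    elif baseline_window == "post":
        vals = series.window(t0, 0, BASELINE_MIN)
    else:
        raise ValueError(f"baseline_window must be 'pre' or 'post', got {baseline_window!r}")
    vals = vals[~np.isnan(vals)]
    if len(vals) < MIN_BASELINE_SAMPLES:
        raise InsufficientBaseline(
            f"only {len(vals)} baseline values at {t0} (need {MIN_BASELINE_SAMPLES})"
        )
    return float(np.median(vals))


def _postprandial_values(series: CgmSeries, t0: pd.Timestamp) -> np.ndarray:
    """y_0..y_n: the value at t0 followed by the 24 window values."""
    vals = series.window(t0, 0, POSTPRANDIAL_MIN + GRID_MINUTES)
    if np.isnan(vals).any():
        raise IncompleteWindow(
            f"postprandial window at {t0} contains missing values; impute first"
        )
    return vals


def compute_ppgr(
    series: CgmSeries, t0: pd.Timestamp, y0: float, clip_negative: bool = False
) -> float:
    """Signed trapezoidal iAUC relative to y0 over (t0, t0+120].

    Units: minutes of relative excursion.  With ``clip_negative``,
    each trapezoid's contribution is floored at zero (classical iAUC).
    """
    if y0 <= 0:
        raise ValueError(f"baseline y0 must be positive, got {y0}")
    y = _postprandial_values(series, t0)
    h = float(GRID_MINUTES)
    terms = (h / 2.0) * (y[:-1] + y[1:] - 2.0 * y0) / y0
    if clip_negative:
        terms = np.clip(terms, 0.0, None)
    return float(terms.sum())


def compute_glu_max(series: CgmSeries, t0: pd.Timestamp, y0: float) -> float:
    """Max glucose over the 24 postprandial grid points minus y0.

    May be negative when the whole window sits below baseline; the
    sign is preserved.
    """
    if y0 <= 0:
        raise ValueError(f"baseline y0 must be positive, got {y0}")
    y = _postprandial_values(series, t0)
    return float(y[1:].max() - y0)


def build_response_table(
    meals: pd.DataFrame,
    imputed: Mapping[str, CgmSeries],
    observed_masks: Mapping[str, np.ndarray] | None = None,
    baseline_window: str = "pre",
    clip_negative: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Compute one ResponseRecord per filtered meal.

    ``observed_masks`` (per patient, True where the pre-imputation
    series was observed) drives the coverage column; without it
    coverage is reported as 1.  Meals whose baseline or window checks
    fail are logged in the returned rejection table, not fatal.
    """
    records, rejects = [], []
    for _, meal in meals.iterrows():
        pid, t0 = str(meal["patient_id"]), meal["meal_time"]
        if pid not in imputed:
            rejects.append((pid, t0, "NO_CGM_SERIES"))
            continue
        s = imputed[pid]
        try:
            y0 = baseline_glucose(s, t0, baseline_window)
            ppgr = compute_ppgr(s, t0, y0, clip_negative)
            glu_max = compute_glu_max(s, t0, y0)
        except InsufficientBaseline:
            rejects.append((pid, t0, "INSUFFICIENT_BASELINE"))
            continue
        except (IncompleteWindow, ValueError) as e:
            rejects.append((pid, t0, "INCOMPLETE_WINDOW"))
            continue
        coverage = 1.0
        if observed_masks is not None and pid in observed_masks:
            k0 = s.slot_of(t0)
            sl = observed_masks[pid][k0 + 1 : k0 + 1 + POSTPRANDIAL_MIN // GRID_MINUTES]
            coverage = float(np.mean(sl)) if len(sl) else 0.0
        records.append(
            ResponseRecord(pid, t0, y0, ppgr, glu_max,
                           POSTPRANDIAL_MIN // GRID_MINUTES, coverage)
        )
    table = pd.DataFrame(
        [
            {
                "patient_id": r.patient_id,
                "meal_time": r.meal_time,
                "y0": r.y0,
                "ppgr": r.ppgr,
                "glu_max": r.glu_max,
                "n_samples": r.n_samples,
                "coverage": r.coverage,
            }
            for r in records
        ]
    )
    reject_table = pd.DataFrame(rejects, columns=["patient_id", "meal_time", "reason"])
    return table, reject_table
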