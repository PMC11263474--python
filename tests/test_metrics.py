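"""Response metrics: baseline median, PPGR trapezoid, Glu_max.

The PPGR implementation is checked against an independent brute-force
oracle: direct trapezoidal integration of (y(t) - y0)/y0 over the
2-hour window, written as an explicit loop.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ppgrlab.cgm import GRID_MINUTES, CgmSeries
from ppgrlab.metrics import (
    InsufficientBaseline,
    IncompleteWindow,
    baseline_glucose,
    build_response_table,
    compute_glu_max,
    compute_ppgr,
)

T0 = pd.Timestamp("2024-01-01 08:00")
START = pd.Timestamp("2024-01-01")


def _series(post_values, baseline=100.0, at_t0=None):
    """Series flat at `baseline` before t0, given values after.

    ``post_values`` are the 24 postprandial grid values; ``at_t0``
    defaults to baseline.
    """
    n_pre = int((T0 - START).total_seconds() / 60) // GRID_MINUTES
    vals = [baseline] * n_pre + [at_t0 if at_t0 is not None else baseline]
    vals += list(post_values)
    return CgmSeries("P", START, np.array(vals, dtype=float))


def ppgr_oracle(y, y0, h=float(GRID_MINUTES)):
    """Explicit-loop trapezoidal integration of (y - y0)/y0."""
    total = 0.0
    for i in range(1, len(y)):
        f_prev = (y[i - 1] - y0) / y0
        f_curr = (y[i] - y0) / y0
        total += h * (f_prev + f_curr) / 2.0
    return total


class TestBaseline:
    def test_median_of_pre_window(self):
        vals = [100, 102, 98, 104, 96, 100]
        n_pre = int((T0 - START).total_seconds() / 60) // GRID_MINUTES
        series_vals = [110.0] * (n_pre - 6) + vals + [120.0] * 25
        s = CgmSeries("P", START, np.array(series_vals, dtype=float))
        assert baseline_glucose(s, T0) == 100.0

    def test_fewer_than_three_values_rejected(self):
        n_pre = int((T0 - START).total_seconds() / 60) // GRID_MINUTES
        vals = [np.nan] * (n_pre - 2) + [90.0, 110.0] + [100.0] * 25
        s = CgmSeries("P", START, np.array(vals))
        with pytest.raises(InsufficientBaseline):
            baseline_glucose(s, T0)

    def test_constant_series(self):
        s = _series([120.0] * 24, baseline=120.0)
        assert baseline_glucose(s, T0) == 120.0

    def test_post_window_variant(self):
        s = _series([130.0] * 24, baseline=100.0, at_t0=130.0)
        assert baseline_glucose(s, T0, baseline_window="post") == 130.0
        assert baseline_glucose(s, T0, baseline_window="pre") == 100.0


class TestPpgr:
    def test_flat_trace_gives_zero(self):
        s = _series([100.0] * 24)
        assert compute_ppgr(s, T0, 100.0) == pytest.approx(0.0, abs=1e-12)

    def test_worked_two_sample_example(self):
        """y0=100, post samples 110 then 120, remainder at y0:
        (5/2)(100+110-200)/100 + (5/2)(110+120-200)/100 = 1.0,
        then 120 falls back to 100 and stays flat: one more trapezoid
        of (5/2)(120+100-200)/100 = 0.5."""
        post = [110.0, 120.0] + [100.0] * 22
        s = _series(post, at_t0=100.0)
        expected = ppgr_oracle(np.array([100.0] + post), 100.0)
        assert compute_ppgr(s, T0, 100.0) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(1.0 + 0.5, abs=1e-12)

    def test_symmetric_excursion_cancels(self):
        # +10 for 11 slots, -10 for 11 slots, endpoints at y0: the
        # signed trapezoids cancel exactly
        post = [110.0] * 11 + [100.0] + [90.0] * 11 + [100.0]
        s = _series(post, at_t0=100.0)
        assert compute_ppgr(s, T0, 100.0) == pytest.approx(0.0, abs=1e-12)

    def test_negative_increments_retained_unless_clipped(self):
        post = [90.0] * 24
        s = _series(post, at_t0=90.0)
        signed = compute_ppgr(s, T0, 100.0)
        assert signed < 0
        clipped = compute_ppgr(s, T0, 100.0, clip_negative=True)
        assert clipped == 0.0

    def test_missing_window_value_rejected(self):
        post = [110.0] * 24
        post[5] = np.nan
        s = _series(post)
        with pytest.raises(IncompleteWindow):
            compute_ppgr(s, T0, 100.0)

    def test_nonpositive_baseline_rejected(self):
        s = _series([110.0] * 24)
        with pytest.raises(ValueError):
            compute_ppgr(s, T0, 0.0)

    def test_matches_oracle_on_random_traces(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            y = rng.uniform(40, 400, 25)
            y0 = rng.uniform(60, 250)
            s = _series(y[1:], at_t0=y[0])
            assert compute_ppgr(s, T0, y0) == pytest.approx(
                ppgr_oracle(y, y0), abs=1e-9
            )

    @given(
        st.lists(st.floats(40, 290), min_size=25, max_size=25),
        st.floats(50, 300),
        st.floats(1.0, 2.0),
    )
    @settings(derandomize=True, max_examples=100)
    def test_scale_invariance(self, y, y0, scale):
        """Multiplying all glucose values and y0 by c>0 leaves the
        ratio-form PPGR unchanged."""
        y = np.array(y)
        s1 = _series(y[1:], at_t0=y[0])
        ys = y * scale
        s2 = _series(ys[1:], baseline=min(ys[0], 400.0), at_t0=ys[0])
        assert compute_ppgr(s2, T0, y0 * scale) == pytest.approx(
            compute_ppgr(s1, T0, y0), rel=1e-9, abs=1e-9
        )

    def test_shift_matches_closed_form(self):
        """Adding c to every y and to y0: glu_max is unchanged; PPGR
        becomes sum h*(y_pair_mean + c - (y0+c))/(y0+c) = PPGR * y0/(y0+c)."""
        rng = np.random.default_rng(3)
        y = rng.uniform(80, 200, 25)
        y0, c = 110.0, 50.0
        base = ppgr_oracle(y, y0)
        shifted = ppgr_oracle(y + c, y0 + c)
        assert shifted == pytest.approx(base * y0 / (y0 + c), rel=1e-9)

    def test_pointwise_increase_weakly_increases_ppgr(self):
        rng = np.random.default_rng(5)
        y = rng.uniform(80, 200, 25)
        y0 = 100.0
        bumped = y.copy()
        bumped[10] += 20.0
        assert ppgr_oracle(bumped, y0) >= ppgr_oracle(y, y0)
        s1, s2 = _series(y[1:], at_t0=y[0]), _series(bumped[1:], at_t0=bumped[0])
        assert compute_ppgr(s2, T0, y0) >= compute_ppgr(s1, T0, y0)


class TestGluMax:
    def test_window_max_minus_baseline(self):
        post = [120.0] * 10 + [180.0] + [110.0] * 13
        s = _series(post)
        assert compute_glu_max(s, T0, 100.0) == 80.0

    def test_flat_trace_gives_zero(self):
        s = _series([100.0] * 24)
        assert compute_glu_max(s, T0, 100.0) == 0.0

    def test_below_baseline_window_keeps_sign(self):
        s = _series([80.0] * 24, at_t0=80.0)
        assert compute_glu_max(s, T0, 100.0) == -20.0

    def test_shift_invariance(self):
        post = list(np.linspace(100, 180, 24))
        s1 = _series(post)
        shifted = [v + 37.0 for v in post]
        s2 = _series(shifted, baseline=137.0, at_t0=137.0)
        assert compute_glu_max(s2, T0, 137.0) == pytest.approx(
            compute_glu_max(s1, T0, 100.0)
        )

    def test_scale_equivariance(self):
        post = list(np.linspace(100, 180, 24))
        s1 = _series(post)
        s2 = _series([2 * v for v in post], baseline=200.0, at_t0=200.0)
        assert compute_glu_max(s2, T0, 200.0) == pytest.approx(
            2 * compute_glu_max(s1, T0, 100.0)
        )


class TestResponseTable:
    def test_gap_free_cohort_keeps_every_meal(self, pipeline_artifacts):
        c = pipeline_artifacts["cohort"]
        kept = pipeline_artifacts["kept"]
        responses, rejects = build_response_table(kept, c.cgm_complete)
        assert len(responses) == len(kept)
        assert len(rejects) == 0

    def test_meal_too_close_to_series_start_rejected(self):
        s = CgmSeries("P", START, np.full(60, 120.0))
        meals = pd.DataFrame(
            [{"patient_id": "P", "meal_time": START + pd.Timedelta(minutes=10)}]
        )
        responses, rejects = build_response_table(meals, {"P": s})
        assert len(responses) == 0
        assert rejects["reason"].iloc[0] == "INSUFFICIENT_BASELINE"

    def test_coverage_reflects_pre_imputation_mask(self):
        n = 24 * 12
        vals = np.full(n, 120.0)
        s = CgmSeries("P", START, vals)
        mask = np.ones(n, dtype=bool)
        k0 = s.slot_of(T0)
        mask[k0 + 1 : k0 + 13] = False  # half the postprandial window unobserved
        meals = pd.DataFrame([{"patient_id": "P", "meal_time": T0}])
        responses, _ = build_response_table(meals, {"P": s}, {"P": mask})
        assert responses["coverage"].iloc[0] == pytest.approx(0.5)
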