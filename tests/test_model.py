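"""Prediction model: splitting, tuning, fitting, Pearson evaluation."""

import numpy as np
import pandas as pd
import pytest

from ppgrlab.features import FEATURE_NAMES
from ppgrlab.model import (
    PPGRRegressor,
    cv_objective,
    evaluate,
    run_comparison,
    split_meals,
)
from ppgrlab.tuning import DEFAULT_SPACE, Dimension, REFERENCE_CONFIG, tune


@pytest.fixture(scope="module")
def small_table():
    """100 meals with a learnable linear signal in a few features."""
    rng = np.random.default_rng(8)
    table = pd.DataFrame(rng.normal(0, 1, (100, 38)), columns=FEATURE_NAMES)
    table["patient_id"] = [f"P{i % 7}" for i in range(100)]
    table["meal_time"] = pd.date_range("2024-01-01", periods=100, freq="4h")
    table["ppgr"] = (
        3.0 * table["carbs"] + 2.0 * table["glucose_at_meal"]
        + rng.normal(0, 0.5, 100)
    )
    table["glu_max"] = 2.0 * table["carbs"] + rng.normal(0, 0.5, 100)
    return table


class TestSplit:
    def test_60_40_partition(self, small_table):
        train, val = split_meals(small_table, seed=0)
        assert len(train) == 60 and len(val) == 40

    def test_same_seed_same_partition(self, small_table):
        a_train, _ = split_meals(small_table, seed=5)
        b_train, _ = split_meals(small_table, seed=5)
        pd.testing.assert_frame_equal(a_train, b_train)

    def test_grouped_mode_separates_patients(self, small_table):
        train, val = split_meals(small_table, seed=0, grouped=True)
        assert not set(train["patient_id"]) & set(val["patient_id"])

    def test_bad_fraction_rejected(self, small_table):
        with pytest.raises(ValueError):
            split_meals(small_table, train_fraction=1.5)


class TestTuning:
    def _quadratic(self, c):
        # smooth objective with optimum inside the space
        return (
            (np.log(c["learning_rate"]) - np.log(0.02)) ** 2
            + ((c["n_estimators"] - 300) / 500) ** 2
            + ((c["subsample"] - 0.7) / 0.3) ** 2
        )

    def test_single_trial_returns_that_config(self):
        best, trace = tune(self._quadratic, n_trials=1, seed=0)
        assert len(trace) == 1
        assert best == trace[0].config

    def test_best_so_far_monotone_and_in_space(self):
        best, trace = tune(self._quadratic, n_trials=40, seed=1)
        losses = [t.loss for t in trace]
        running = np.minimum.accumulate(losses)
        assert (np.diff(running) <= 0).all()
        for t in trace:
            for name, dim in DEFAULT_SPACE.items():
                assert dim.contains(t.config[name])

    def test_space_contains_reference_optimum(self):
        for name, value in REFERENCE_CONFIG.items():
            assert DEFAULT_SPACE[name].contains(value)

    def test_tpe_beats_pure_startup_on_smooth_objective(self):
        _, trace = tune(self._quadratic, n_trials=60, seed=2)
        startup = min(t.loss for t in trace[:10])
        final = min(t.loss for t in trace)
        assert final <= startup

    def test_integer_dimensions_yield_integers(self):
        _, trace = tune(self._quadratic, n_trials=20, seed=3)
        for t in trace:
            assert float(t.config["n_estimators"]).is_integer()
            assert float(t.config["max_depth"]).is_integer()

    def test_degenerate_target_rejected(self, small_table):
        model = PPGRRegressor(n_trials=1, seed=0)
        with pytest.raises(ValueError, match="zero variance"):
            model.fit(small_table[FEATURE_NAMES], np.ones(len(small_table)))


class TestFit:
    def test_constant_target_constant_prediction(self, small_table):
        # degenerate for tuning but legal with a fixed config
        y = np.full(len(small_table), 5.0)
        model = PPGRRegressor(config=REFERENCE_CONFIG, seed=0)
        model.fit(small_table[FEATURE_NAMES], y)
        pred = model.predict(small_table[FEATURE_NAMES])
        np.testing.assert_allclose(pred, 5.0, atol=1e-6)

    def test_carb_only_sees_exactly_one_feature(self, small_table):
        model = PPGRRegressor(variant="carb_only", config=REFERENCE_CONFIG, seed=0)
        model.fit(small_table[FEATURE_NAMES], small_table["ppgr"].to_numpy())
        assert model.feature_names_ == ["carbs"]

    def test_save_load_round_trip_identical_predictions(self, small_table, tmp_path):
        model = PPGRRegressor(variant="full", config=REFERENCE_CONFIG, seed=0)
        model.fit(small_table[FEATURE_NAMES], small_table["ppgr"].to_numpy())
        path = tmp_path / "model.txt"
        model.save(path)
        reloaded = PPGRRegressor.load(path)
        np.testing.assert_array_equal(
            model.predict(small_table[FEATURE_NAMES]),
            reloaded.predict(small_table[FEATURE_NAMES]),
        )

    def test_refit_same_seed_identical(self, small_table):
        X, y = small_table[FEATURE_NAMES], small_table["ppgr"].to_numpy()
        a = PPGRRegressor(config=REFERENCE_CONFIG, seed=0).fit(X, y)
        b = PPGRRegressor(config=REFERENCE_CONFIG, seed=0).fit(X, y)
        np.testing.assert_array_equal(a.predict(X), b.predict(X))

    def test_sklearn_get_set_params(self):
        model = PPGRRegressor(variant="carb_only", n_trials=3)
        params = model.get_params()
        assert params["variant"] == "carb_only"
        model.set_params(variant="full")
        assert model.variant == "full"


class TestEvaluate:
    def _fitted(self, small_table):
        model = PPGRRegressor(config=REFERENCE_CONFIG, seed=0)
        model.fit(small_table[FEATURE_NAMES], small_table["ppgr"].to_numpy())
        return model

    def test_perfect_predictions_r_one(self, small_table):
        model = self._fitted(small_table)
        y = model.predict(small_table[FEATURE_NAMES])
        ev = evaluate(model, small_table[FEATURE_NAMES], y)
        assert ev["pearson_r"] == pytest.approx(1.0)
        assert ev["explained_variance"] == pytest.approx(1.0)

    def test_anti_predictions_r_minus_one(self, small_table):
        model = self._fitted(small_table)
        y = -model.predict(small_table[FEATURE_NAMES])
        ev = evaluate(model, small_table[FEATURE_NAMES], y)
        assert ev["pearson_r"] == pytest.approx(-1.0)

    def test_pearson_matches_covariance_oracle(self, small_table):
        model = self._fitted(small_table)
        y = small_table["glu_max"].to_numpy()
        pred = model.predict(small_table[FEATURE_NAMES])
        ev = evaluate(model, small_table[FEATURE_NAMES], y)
        cov = np.mean((pred - pred.mean()) * (y - y.mean()))
        oracle = cov / (pred.std() * y.std())
        assert ev["pearson_r"] == pytest.approx(oracle, abs=1e-12)

    def test_too_few_validation_meals_rejected(self, small_table):
        model = self._fitted(small_table)
        with pytest.raises(ValueError):
            evaluate(model, small_table[FEATURE_NAMES].head(2), np.zeros(2))

    def test_degenerate_predictions_flagged_not_nan(self, small_table):
        model = PPGRRegressor(
            config={**REFERENCE_CONFIG, "n_estimators": 1, "min_child_samples": 200},
            seed=0,
        )
        model.fit(small_table[FEATURE_NAMES], small_table["ppgr"].to_numpy())
        ev = evaluate(model, small_table[FEATURE_NAMES], small_table["ppgr"].to_numpy())
        if ev["degenerate"]:
            assert ev["pearson_r"] is None


class TestComparison:
    def test_variant_ordering_on_default_cohort(self, comparison_results):
        """Validation Pearson r must rank full > insulin_baseline >
        carb_only for both response targets, mirroring the expected
        value of richer clinical context."""
        for target in ("ppgr", "glu_max"):
            r = {
                v: comparison_results[(target, v)].evaluation["pearson_r"]
                for v in ("carb_only", "insulin_baseline", "full")
            }
            assert r["full"] > r["insulin_baseline"] > r["carb_only"], (target, r)

    def test_all_cells_share_one_split(self, comparison_results):
        sizes = {
            (res.n_train, res.n_val) for res in comparison_results.values()
        }
        assert len(sizes) == 1

    def test_cv_objective_penalises_noise_only_features(self, small_table):
        X = small_table[FEATURE_NAMES]
        y = small_table["ppgr"].to_numpy()
        good = cv_objective(X, y, REFERENCE_CONFIG, seed=0)
        shuffled = y.copy()
        np.random.default_rng(0).shuffle(shuffled)
        bad = cv_objective(X, shuffled, REFERENCE_CONFIG, seed=0)
        assert good < bad
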