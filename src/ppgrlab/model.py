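"""Gradient-boosted PPGR / Glu_max prediction with tuned LightGBM.

Three model variants are compared on one shared 60/40 meal split:

* ``carb_only`` — carbohydrate grams as the sole input (the classical
  carbohydrate-counting heuristic);
* ``insulin_baseline`` — carbohydrates, pre-meal bolus dose and
  glucose at meal initiation (emulating the standard of care for
  insulin dosing);
* ``full`` — all 38 features.

Each variant's LightGBM regressor is tuned by TPE + random search
(see :mod:`ppgrlab.tuning`) against 5-fold cross-validated squared
error on a seeded subsample of the training meals, then refit on the
full training side and scored on the validation side by the Pearson
correlation between predicted and observed responses; explained
variance is reported as r².
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import lightgbm as lgb
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.model_selection import KFold
from sklearn.utils.validation import check_is_fitted

from .features import FEATURE_NAMES, VARIANTS, variant_subset
from .tuning import DEFAULT_SPACE, Dimension, Trial, tune

TARGETS = ("ppgr", "glu_max")


def split_meals(
    table: pd.DataFrame,
    train_fraction: float = 0.6,
    seed: int = 0,
    grouped: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Random 60/40 per-meal partition of the feature table.

    ``grouped=True`` partitions whole patients instead, so no patient
    appears on both sides (leakage-free alternative).
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie strictly in (0, 1)")
    if len(table) < 10:
        raise ValueError("need at least 10 meals to split")
    rng = np.random.default_rng(seed)
    if grouped:
        patients = np.array(sorted(table["patient_id"].unique()))
        rng.shuffle(patients)
        n_train = max(1, int(round(train_fraction * len(patients))))
        train_p = set(patients[:n_train])
        is_train = table["patient_id"].isin(train_p).to_numpy()
    else:
        idx = rng.permutation(len(table))
        n_train = int(round(train_fraction * len(table)))
        is_train = np.zeros(len(table), dtype=bool)
        is_train[idx[:n_train]] = True
    return (
        table[is_train].reset_index(drop=True),
        table[~is_train].reset_index(drop=True),
    )


def _lgbm(config: dict[str, float], seed: int) -> lgb.LGBMRegressor:
    return lgb.LGBMRegressor(
        learning_rate=config["learning_rate"],
        n_estimators=int(config["n_estimators"]),
        max_depth=int(config["max_depth"]),
        colsample_bytree=config["colsample_bytree"],
        min_child_samples=int(config["min_child_samples"]),
        num_leaves=int(config["num_leaves"]),
        subsample=config["subsample"],
        subsample_freq=1,
        random_state=seed,
        deterministic=True,
        force_row_wise=True,
        n_jobs=1,
        verbose=-1,
    )


def cv_objective(
    X: pd.DataFrame,
    y: np.ndarray,
    config: dict[str, float],
    seed: int,
    n_folds: int = 5,
    subsample_fraction: float = 1.0,
) -> float:
    """5-fold CV mean squared error, optionally on a data subsample."""
    rng = np.random.default_rng(seed)
    if subsample_fraction < 1.0:
        n = max(int(round(subsample_fraction * len(X))), 2 * n_folds)
        keep = rng.choice(len(X), size=min(n, len(X)), replace=False)
        X, y = X.iloc[keep], y[keep]
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    errs = []
    for tr, va in kf.split(X):
        model = _lgbm(config, seed)
        model.fit(X.iloc[tr], y[tr])
        pred = model.predict(X.iloc[va])
        errs.append(float(np.mean((pred - y[va]) ** 2)))
    return float(np.mean(errs))


class PPGRRegressor(RegressorMixin, BaseEstimator):
    """Tuned LightGBM regressor for postprandial response targets.

    Parameters
    ----------
    variant : {'carb_only', 'insulin_baseline', 'full'}
        Feature subset the model trains on.
    config : dict or None
        Fixed hyperparameters; when None and ``n_trials`` > 0 the
        model is tuned by TPE + random search at fit time, otherwise
        the reference optimum configuration is used.
    n_trials : int
        Tuning budget (0 disables tuning).
    subsample_fraction : float
        Share of training meals used by the tuning objective — tuning
        on a representative subsample in place of the full training
        set cuts search time.
    seed : int
        Drives the tuner, CV folds and LightGBM.

    Attributes
    ----------
    booster_ : fitted LGBMRegressor
    best_config_ : dict — hyperparameters actually used
    tuning_trace_ : list[Trial] — per-trial losses (empty if not tuned)
    feature_names_ : list[str]
    """

    def __init__(
        self,
        variant: str = "full",
        config: dict | None = None,
        n_trials: int = 25,
        subsample_fraction: float = 0.8,
        space: dict[str, Dimension] | None = None,
        seed: int = 0,
    ):
        self.variant = variant
        self.config = config
        self.n_trials = n_trials
        self.subsample_fraction = subsample_fraction
        self.space = space
        self.seed = seed

    def fit(self, X: pd.DataFrame, y) -> "PPGRRegressor":
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        X = variant_subset(pd.DataFrame(X), self.variant)
        if X.shape[1] == 0:
            raise ValueError("empty feature set")
        y = np.asarray(y, dtype=float)
        space = self.space or DEFAULT_SPACE
        if self.config is not None:
            self.best_config_, self.tuning_trace_ = dict(self.config), []
        elif self.n_trials > 0:
            if np.std(y) == 0:
                raise ValueError("degenerate training target: zero variance")
            self.best_config_, self.tuning_trace_ = tune(
                lambda c: cv_objective(
                    X, y, c, self.seed, subsample_fraction=self.subsample_fraction
                ),
                space=space,
                n_trials=self.n_trials,
                seed=self.seed,
            )
        else:
            from .tuning import REFERENCE_CONFIG

            self.best_config_, self.tuning_trace_ = dict(REFERENCE_CONFIG), []
        self.booster_ = _lgbm(self.best_config_, self.seed)
        self.booster_.fit(X, y)
        self.feature_names_ = list(X.columns)
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        check_is_fitted(self, "booster_")
        X = pd.DataFrame(X)
        if set(self.feature_names_).issubset(X.columns):
            X = X[self.feature_names_]
        return self.booster_.predict(X)

    def save(self, path: str | Path) -> None:
        check_is_fitted(self, "booster_")
        path = Path(path)
        self.booster_.booster_.save_model(str(path))
        meta = {
            "variant": self.variant,
            "config": self.best_config_,
            "features": self.feature_names_,
            "seed": self.seed,
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta))

    @classmethod
    def load(cls, path: str | Path) -> "PPGRRegressor":
        path = Path(path)
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        obj = cls(variant=meta["variant"], config=meta["config"], seed=meta["seed"])
        obj.best_config_ = meta["config"]
        obj.tuning_trace_ = []
        obj.feature_names_ = meta["features"]
        booster = lgb.Booster(model_file=str(path))
        obj.booster_ = _BoosterAdapter(booster)
        return obj


class _BoosterAdapter:
    """Duck-typed stand-in so a reloaded Booster predicts like the sklearn wrapper."""

    def __init__(self, booster: lgb.Booster):
        self.booster_ = booster

    def predict(self, X, **kw):
        return self.booster_.predict(X, **kw)


def evaluate(model: PPGRRegressor, X_val: pd.DataFrame, y_val) -> dict:
    """Pearson r between predictions and observations, p-value, r²."""
    y_val = np.asarray(y_val, dtype=float)
    if len(y_val) < 3:
        raise ValueError("need at least 3 validation meals")
    pred = model.predict(X_val)
    if np.all(pred == pred[0]) or np.all(y_val == y_val[0]):
        return {
            "pearson_r": None,
            "p_value": None,
            "explained_variance": None,
            "degenerate": True,
            "n_val": len(y_val),
        }
    r, p = stats.pearsonr(pred, y_val)
    return {
        "pearson_r": float(r),
        "p_value": float(p),
        "explained_variance": float(r**2),
        "degenerate": False,
        "n_val": len(y_val),
    }


@dataclass
class FitResult:
    target: str
    variant: str
    best_config: dict
    model: PPGRRegressor
    tuning_trace: list
    evaluation: dict
    n_train: int
    n_val: int

    def summary(self) -> dict:
        return {
            "target": self.target,
            "variant": self.variant,
            "best_config": self.best_config,
            "pearson_r": self.evaluation["pearson_r"],
            "p_value": self.evaluation["p_value"],
            "explained_variance": self.evaluation["explained_variance"],
            "n_train": self.n_train,
            "n_val": self.n_val,
        }


def run_comparison(
    table: pd.DataFrame,
    seed: int = 0,
    n_trials: int = 25,
    train_fraction: float = 0.6,
    grouped: bool = False,
    subsample_fraction: float = 0.8,
) -> dict[tuple[str, str], FitResult]:
    """Fit and score all 3 variants x 2 targets on one shared split."""
    train, val = split_meals(table, train_fraction, seed, grouped)
    results: dict[tuple[str, str], FitResult] = {}
    for target in TARGETS:
        for variant in VARIANTS:
            model = PPGRRegressor(
                variant=variant,
                n_trials=n_trials,
                subsample_fraction=subsample_fraction,
                seed=seed,
            )
            model.fit(train[FEATURE_NAMES], train[target].to_numpy())
            ev = evaluate(model, val[FEATURE_NAMES], val[target].to_numpy())
            results[(target, variant)] = FitResult(
                target=target,
                variant=variant,
                best_config=model.best_config_,
                model=model,
                tuning_trace=model.tuning_trace_,
                evaluation=ev,
                n_train=len(train),
                n_val=len(val),
            )
    return results
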