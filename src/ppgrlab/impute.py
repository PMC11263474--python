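"""Gap imputation for CGM traces: GAIN, KNN and linear baselines.

GAIN (Generative Adversarial Imputation Network) trains two small
fully connected networks against each other.  The generator G receives
the observed data matrix X~ (noise Z substituted at missing slots) and
the mask M (1 = observed) and outputs a completed matrix
X_bar = G(X~, M, (1-M) .* Z).  The discriminator D receives the
completed matrix together with a *hint* H — the true mask with a
random subset of entries blanked to 0.5 — and predicts, per entry,
the probability that the entry was observed.  D is trained by
cross-entropy toward M; G is trained to fool D on missing entries
plus a weighted reconstruction loss on observed entries.

CGM traces enter as a patient-day x 288 matrix (one column per
within-day 5-minute slot) so the networks can exploit time-of-day
correlation.  Values are min-max normalised to [0, 1] on observed
entries; imputations are de-normalised and clipped to the sensor
range.  Observed entries are always passed through untouched:
output = M .* X~ + (1-M) .* X_bar.

The networks are plain numpy with hand-written backpropagation and
Adam — small enough (two hidden layers of width 288) that no deep
learning framework is warranted, and fully deterministic under a seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.impute import KNNImputer
from sklearn.utils.validation import check_is_fitted

from .cgm import GLUCOSE_MAX, GLUCOSE_MIN, GRID_MINUTES, CgmSeries

logger = logging.getLogger(__name__)

SLOTS_PER_DAY = 24 * 60 // GRID_MINUTES  # 288


# ---------------------------------------------------------------------------
# matrix layout


def matrixise(
    series: Mapping[str, CgmSeries]
) -> tuple[np.ndarray, np.ndarray, dict, list[tuple[str, int]]]:
    """Stack series into a (patient-day x 288) matrix.

    Returns (data, mask, norm_params, row_index) where data is min-max
    normalised to [0, 1] over observed entries (NaN at missing), mask
    is 1.0 where observed, norm_params holds the inverse transform and
    row_index maps each row to (patient_id, day_number).  Rows with no
    observed entry are dropped with a warning.
    """
    rows, index = [], []
    for pid, s in series.items():
        n_days = int(np.ceil(len(s.values) / SLOTS_PER_DAY))
        padded = np.full(n_days * SLOTS_PER_DAY, np.nan)
        padded[: len(s.values)] = s.values
        for d in range(n_days):
            row = padded[d * SLOTS_PER_DAY : (d + 1) * SLOTS_PER_DAY]
            if np.isnan(row).all():
                logger.warning("dropping fully missing day %d of patient %s", d, pid)
                continue
            rows.append(row)
            index.append((pid, d))
    data = np.vstack(rows)
    lo = float(np.nanmin(data))
    hi = float(np.nanmax(data))
    span = hi - lo if hi > lo else 1.0
    norm = {"lo": lo, "span": span}
    mask = (~np.isnan(data)).astype(float)
    return (data - lo) / span, mask, norm, index


def denormalise(x: np.ndarray, norm: dict) -> np.ndarray:
    return x * norm["span"] + norm["lo"]


# ---------------------------------------------------------------------------
# tiny MLP with manual backprop + Adam


class _MLP:
    """Fully connected net, ReLU hidden layers, sigmoid output."""

    def __init__(self, dims: Sequence[int], rng: np.random.Generator):
        self.W = [
            rng.normal(0.0, np.sqrt(2.0 / dims[i]), (dims[i], dims[i + 1]))
            for i in range(len(dims) - 1)
        ]
        self.b = [np.zeros(dims[i + 1]) for i in range(len(dims) - 1)]
        self._adam = [
            {"mW": np.zeros_like(W), "vW": np.zeros_like(W),
             "mb": np.zeros_like(b), "vb": np.zeros_like(b)}
            for W, b in zip(self.W, self.b)
        ]
        self._t = 0

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._acts = [x]
        h = x
        last = len(self.W) - 1
        for i, (W, b) in enumerate(zip(self.W, self.b)):
            z = h @ W + b
            h = 1.0 / (1.0 + np.exp(-z)) if i == last else np.maximum(z, 0.0)
            self._acts.append(h)
        return h

    def backward(self, dL_dout_pre: np.ndarray) -> np.ndarray:
        """Backprop from dL/dz of the output layer (pre-sigmoid)."""
        grads = []
        delta = dL_dout_pre
        for i in reversed(range(len(self.W))):
            a_prev = self._acts[i]
            gW = a_prev.T @ delta
            gb = delta.sum(axis=0)
            grads.append((gW, gb))
            if i > 0:
                delta = (delta @ self.W[i].T) * (self._acts[i] > 0)
        self._grads = list(reversed(grads))
        # gradient w.r.t. the input, for chaining through G's output
        return delta @ self.W[0].T

    def step(self, lr: float, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self._t += 1
        for (gW, gb), W, b, st in zip(self._grads, self.W, self.b, self._adam):
            st["mW"] = beta1 * st["mW"] + (1 - beta1) * gW
            st["vW"] = beta2 * st["vW"] + (1 - beta2) * gW**2
            st["mb"] = beta1 * st["mb"] + (1 - beta1) * gb
            st["vb"] = beta2 * st["vb"] + (1 - beta2) * gb**2
            corr1, corr2 = 1 - beta1**self._t, 1 - beta2**self._t
            W -= lr * (st["mW"] / corr1) / (np.sqrt(st["vW"] / corr2) + eps)
            b -= lr * (st["mb"] / corr1) / (np.sqrt(st["vb"] / corr2) + eps)


# ---------------------------------------------------------------------------
# GAIN estimator


class GAINImputer(TransformerMixin, BaseEstimator):
    """Adversarial imputer for matrices with missing entries (NaN).

    sklearn-style: ``fit(X)`` trains generator and discriminator on
    the observed pattern of ``X``; ``transform(X)`` returns the
    completed matrix with observed entries untouched.  Values are
    expected in mg/dL; normalisation is internal.

    Parameters
    ----------
    hidden : int or None
        Width of the two hidden layers; defaults to the column count.
    hint_rate : float
        Probability an entry of the true mask is revealed to the
        discriminator (unrevealed entries get 0.5).
    alpha_rec : float
        Weight of the observed-entry reconstruction loss in the
        generator objective.
    epochs, batch_size, learning_rate, seed
        Optimisation settings; training is deterministic under seed.
    """

    def __init__(
        self,
        hidden: int | None = None,
        hint_rate: float = 0.9,
        alpha_rec: float = 100.0,
        epochs: int = 200,
        batch_size: int = 64,
        learning_rate: float = 1e-3,
        seed: int = 0,
    ):
        self.hidden = hidden
        self.hint_rate = hint_rate
        self.alpha_rec = alpha_rec
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.seed = seed

    def _check_params(self):
        if not 0.0 <= self.hint_rate <= 1.0:
            raise ValueError("hint_rate must lie in [0, 1]")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.alpha_rec <= 0:
            raise ValueError("alpha_rec must be > 0")

    def fit(self, X: np.ndarray, y=None) -> "GAINImputer":
        self._check_params()
        X = np.asarray(X, dtype=float)
        if X.size == 0:
            raise ValueError("empty matrix")
        mask = (~np.isnan(X)).astype(float)
        if mask.min() == 1.0:
            # nothing missing: trains on synthetic dropout of observed cells
            pass
        if mask.max() == 0.0:
            raise ValueError("matrix has no observed entries")

        lo, hi = np.nanmin(X), np.nanmax(X)
        span = (hi - lo) if hi > lo else 1.0
        self.norm_ = {"lo": float(lo), "span": float(span)}
        Xn = (X - lo) / span
        Xn = np.nan_to_num(Xn, nan=0.0)

        n, d = X.shape
        h = self.hidden or d
        rng = np.random.default_rng(self.seed)
        self.G_ = _MLP([2 * d, h, h, d], rng)
        self.D_ = _MLP([2 * d, h, h, d], rng)

        batch = min(self.batch_size, n)
        self.loss_history_ = []
        for epoch in range(self.epochs):
            order = rng.permutation(n)
            epoch_rec, epoch_batches = 0.0, 0
            for start in range(0, n, batch):
                idx = order[start : start + batch]
                m = mask[idx]
                x = Xn[idx]
                z = rng.uniform(0.0, 0.01, x.shape)
                x_tilde = m * x + (1 - m) * z

                # --- discriminator step
                x_bar = self.G_.forward(np.hstack([x_tilde, m]))
                x_hat = m * x_tilde + (1 - m) * x_bar
                b = (rng.random(m.shape) < self.hint_rate).astype(float)
                hint = b * m + 0.5 * (1 - b)
                d_prob = self.D_.forward(np.hstack([x_hat, hint]))
                # cross-entropy toward the true mask; dL/dz = (p - m)/N
                self.D_.backward((d_prob - m) / m.size)
                self.D_.step(self.learning_rate)

                # --- generator step
                x_bar = self.G_.forward(np.hstack([x_tilde, m]))
                x_hat = m * x_tilde + (1 - m) * x_bar
                d_prob = self.D_.forward(np.hstack([x_hat, hint]))
                # adversarial: G wants D to call missing entries observed
                dL_dz_D = (-(1 - m) * (1 - d_prob)) / max((1 - m).sum(), 1.0)
                dL_dxhat = self.D_.backward(dL_dz_D)[:, :d]
                n_obs = max(m.sum(), 1.0)
                rec_err = m * (x_bar - x)
                dL_dxbar = (1 - m) * dL_dxhat + self.alpha_rec * 2.0 * rec_err / n_obs
                # chain through G's output sigmoid
                dL_dzG = dL_dxbar * x_bar * (1.0 - x_bar)
                self.G_.backward(dL_dzG)
                self.G_.step(self.learning_rate)

                rec_loss = float((rec_err**2).sum() / n_obs)
                if not np.isfinite(rec_loss):
                    raise FloatingPointError(
                        f"non-finite generator loss at epoch {epoch}"
                    )
                epoch_rec += rec_loss
                epoch_batches += 1
            self.loss_history_.append(epoch_rec / max(epoch_batches, 1))
        self.n_features_in_ = d
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "G_")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} columns, got {X.shape[1]}"
            )
        mask = (~np.isnan(X)).astype(float)
        Xn = (X - self.norm_["lo"]) / self.norm_["span"]
        Xn = np.nan_to_num(Xn, nan=0.0)
        rng = np.random.default_rng(self.seed + 1)
        z = rng.uniform(0.0, 0.01, X.shape)
        x_tilde = mask * Xn + (1 - mask) * z
        x_bar = self.G_.forward(np.hstack([x_tilde, mask]))
        filled = x_bar * self.norm_["span"] + self.norm_["lo"]
        filled = np.clip(filled, GLUCOSE_MIN, GLUCOSE_MAX)
        out = np.where(mask == 1.0, X, filled)
        return out


# ---------------------------------------------------------------------------
# baseline imputers


def knn_impute(matrix: np.ndarray, k: int = 5) -> np.ndarray:
    """Fill NaNs with the mean of the k nearest rows (nan-euclidean).

    Distances ignore mutually missing columns and are rescaled by the
    shared-column count.  Observed entries are preserved exactly.
    Falls back to the column mean when no neighbour has the value.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    X = np.asarray(matrix, dtype=float)
    filled = KNNImputer(n_neighbors=k).fit_transform(X)
    # KNNImputer drops all-NaN columns; restore shape via column means
    if filled.shape != X.shape:
        out = X.copy()
        col_ok = ~np.isnan(X).all(axis=0)
        out[:, col_ok] = np.where(np.isnan(X[:, col_ok]), filled, X[:, col_ok])
        return out
    return np.where(np.isnan(X), filled, X)


def column_mean_impute(matrix: np.ndarray) -> np.ndarray:
    """Fill each NaN with its column's observed mean."""
    X = np.asarray(matrix, dtype=float)
    means = np.nanmean(X, axis=0)
    return np.where(np.isnan(X), means, X)


def linear_interpolate(series: CgmSeries) -> CgmSeries:
    """Linearly interpolate interior gaps in time; extend at the edges.

    Leading/trailing gaps take the nearest observed value.  Requires
    at least one observed value.
    """
    vals = series.values
    obs = np.flatnonzero(~np.isnan(vals))
    if obs.size == 0:
        raise ValueError("cannot interpolate an all-missing series")
    idx = np.arange(len(vals))
    filled = np.interp(idx, obs, vals[obs])
    return CgmSeries(series.patient_id, series.start, filled)


def linear_interpolate_matrix(matrix: np.ndarray) -> np.ndarray:
    """Row-wise linear interpolation (within-day, matching the layout)."""
    X = np.asarray(matrix, dtype=float)
    out = X.copy()
    idx = np.arange(X.shape[1])
    for i in range(X.shape[0]):
        obs = np.flatnonzero(~np.isnan(X[i]))
        if obs.size == 0:
            continue
        out[i] = np.interp(idx, obs, X[i, obs])
    return out


# ---------------------------------------------------------------------------
# masking evaluation protocol


@dataclass
class ImputationEvaluation:
    method: str
    mae_mgdl: float
    n_masked: int


def evaluate_masking(
    matrix: np.ndarray,
    fraction: float,
    methods: Mapping[str, Callable[[np.ndarray], np.ndarray]],
    seed: int = 0,
) -> dict[str, ImputationEvaluation]:
    """Masked-MAE benchmark of imputation methods on complete data.

    A fraction of cells of the fully observed ``matrix`` is hidden
    uniformly at random; every method receives the *identical* masked
    matrix and its imputations are scored as

        MAE = sum_{(i,j) masked} |x_hat_ij - x_ij| / n_masked

    in the units of the input (mg/dL).  Each method must preserve
    observed entries exactly; a violation raises.
    """
    X = np.asarray(matrix, dtype=float)
    if np.isnan(X).any():
        raise ValueError("evaluation matrix must be fully observed")
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie strictly in (0, 1)")
    rng = np.random.default_rng(seed)
    hide = rng.random(X.shape) < fraction
    if not hide.any():
        raise ValueError("fraction too small: no cells masked")
    masked = X.copy()
    masked[hide] = np.nan

    results = {}
    for name, method in methods.items():
        completed = method(masked.copy())
        if not np.allclose(completed[~hide], X[~hide], rtol=0, atol=0):
            raise AssertionError(f"method {name!r} modified observed entries")
        mae = float(np.abs(completed[hide] - X[hide]).mean())
        results[name] = ImputationEvaluation(name, mae, int(hide.sum()))
    return results


def default_methods(
    gain_epochs: int = 150, seed: int = 0, k: int = 5
) -> dict[str, Callable[[np.ndarray], np.ndarray]]:
    """The benchmark suite: GAIN, KNN, linear and column mean."""

    def gain(m: np.ndarray) -> np.ndarray:
        imp = GAINImputer(epochs=gain_epochs, seed=seed)
        return imp.fit(m).transform(m)

    return {
        "gain": gain,
        "knn": lambda m: knn_impute(m, k=k),
        "linear": linear_interpolate_matrix,
        "column_mean": column_mean_impute,
    }


def impute_series(
    series: Mapping[str, CgmSeries],
    method: str = "gain",
    gain_epochs: int = 150,
    seed: int = 0,
    k: int = 5,
) -> dict[str, CgmSeries]:
    """Impute every patient's gaps and return completed series."""
    if method == "linear":
        return {pid: linear_interpolate(s) for pid, s in series.items()}
    data_n, mask, norm, index = matrixise(series)
    data = denormalise(np.where(mask == 1.0, data_n, np.nan), norm)
    data[mask == 0.0] = np.nan
    if method == "gain":
        completed = GAINImputer(epochs=gain_epochs, seed=seed).fit(data).transform(data)
    elif method == "knn":
        completed = knn_impute(data, k=k)
    elif method == "column_mean":
        completed = column_mean_impute(data)
    else:
        raise ValueError(f"unknown imputation method {method!r}")
    # any cell still NaN (e.g. all-missing column): fall back to overall mean
    completed = np.where(np.isnan(completed), np.nanmean(data), completed)

    out: dict[str, CgmSeries] = {}
    for pid, s in series.items():
        n = len(s.values)
        vals = np.full(int(np.ceil(n / SLOTS_PER_DAY)) * SLOTS_PER_DAY, np.nan)
        for row, (rpid, day) in zip(completed, index):
            if rpid == pid:
                vals[day * SLOTS_PER_DAY : (day + 1) * SLOTS_PER_DAY] = row
        vals = vals[:n]
        # days dropped in matrixise stay missing; interpolate as last resort
        if np.isnan(vals).any() and (~np.isnan(vals)).any():
            obs = np.flatnonzero(~np.isnan(vals))
            vals = np.interp(np.arange(n), obs, vals[obs])
        out[pid] = CgmSeries(s.patient_id, s.start, np.clip(vals, GLUCOSE_MIN, GLUCOSE_MAX))
    return out
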