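"""Hyperparameter search: Tree-structured Parzen Estimator + random search.

TPE is a sequential model-based optimiser.  After some random startup
trials, the observed (config, loss) pairs are split at the gamma
quantile of the losses into a "good" set and a "bad" set; for each
hyperparameter independently, Parzen (kernel-density) estimators l(x)
over good values and g(x) over bad values are built, candidate values
are drawn from l, and the candidate maximising the density ratio
l(x)/g(x) is proposed.  A configured share of trials bypasses TPE and
samples uniformly from the space — the random-search component that
guards against the Parzen model locking onto a local optimum.

The implementation is factorised (one 1-D estimator per parameter),
with Gaussian kernels on a log scale where the prior is log-uniform,
and discretisation for integer parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np


@dataclass(frozen=True)
class Dimension:
    """One hyperparameter's prior: uniform or log-uniform, float or int."""

    low: float
    high: float
    log: bool = False
    integer: bool = False

    def __post_init__(self):
        if not self.low < self.high:
            raise ValueError("dimension needs low < high")
        if self.log and self.low <= 0:
            raise ValueError("log dimension needs low > 0")

    def sample(self, rng: np.random.Generator) -> float:
        if self.log:
            v = float(np.exp(rng.uniform(np.log(self.low), np.log(self.high))))
        else:
            v = float(rng.uniform(self.low, self.high))
        return float(int(round(v))) if self.integer else v

    def contains(self, v: float) -> bool:
        return self.low <= v <= self.high

    def _to_internal(self, v: np.ndarray) -> np.ndarray:
        return np.log(v) if self.log else np.asarray(v, dtype=float)

    def _from_internal(self, u: float) -> float:
        v = float(np.exp(u)) if self.log else float(u)
        v = min(max(v, self.low), self.high)
        return float(int(round(v))) if self.integer else v


#: default search space; contains the reference optimum
#: (learning_rate 0.009, n_estimators 345, max_depth 5, colsample_bytree
#: 0.75, min_child_samples 2, num_leaves 36, subsample 0.69)
DEFAULT_SPACE: dict[str, Dimension] = {
    "learning_rate": Dimension(1e-3, 0.3, log=True),
    "n_estimators": Dimension(50, 1000, integer=True),
    "max_depth": Dimension(2, 12, integer=True),
    "colsample_bytree": Dimension(0.4, 1.0),
    "min_child_samples": Dimension(1, 50, integer=True),
    "num_leaves": Dimension(8, 256, integer=True),
    "subsample": Dimension(0.4, 1.0),
}

#: the reference optimum configuration reported for the full model
REFERENCE_CONFIG: dict[str, float] = {
    "learning_rate": 0.009,
    "n_estimators": 345,
    "max_depth": 5,
    "colsample_bytree": 0.75,
    "min_child_samples": 2,
    "num_leaves": 36,
    "subsample": 0.69,
}


@dataclass
class Trial:
    config: dict[str, float]
    loss: float


def _parzen_sample_and_score(
    dim: Dimension,
    good: np.ndarray,
    bad: np.ndarray,
    rng: np.random.Generator,
    n_candidates: int = 24,
) -> float:
    """Draw candidates from the good-density KDE, score by l(x)/g(x)."""
    g = dim._to_internal(good)
    b = dim._to_internal(bad)
    span = dim._to_internal(np.array([dim.high]))[0] - dim._to_internal(
        np.array([max(dim.low, 1e-12) if dim.log else dim.low])
    )[0]
    bw_g = max(1.06 * np.std(g) * len(g) ** -0.2, 0.02 * abs(span), 1e-6)
    bw_b = max(1.06 * np.std(b) * len(b) ** -0.2, 0.02 * abs(span), 1e-6)
    centers = g[rng.integers(0, len(g), n_candidates)]
    cands = centers + rng.normal(0.0, bw_g, n_candidates)

    def density(x: np.ndarray, mu: np.ndarray, bw: float) -> np.ndarray:
        z = (x[:, None] - mu[None, :]) / bw
        return np.exp(-0.5 * z**2).sum(axis=1) / (len(mu) * bw)

    l_x = density(cands, g, bw_g)
    g_x = density(cands, b, bw_b) + 1e-12
    best = cands[int(np.argmax(l_x / g_x))]
    return dim._from_internal(best)


def suggest(
    space: dict[str, Dimension],
    history: list[Trial],
    rng: np.random.Generator,
    gamma: float = 0.25,
    n_startup: int = 10,
    random_share: float = 0.25,
) -> dict[str, float]:
    """Propose the next configuration (TPE or uniform random)."""
    if len(history) < n_startup or rng.random() < random_share:
        return {name: dim.sample(rng) for name, dim in space.items()}
    losses = np.array([t.loss for t in history])
    cut = np.quantile(losses, gamma)
    good_idx = losses <= cut
    if good_idx.sum() < 2 or (~good_idx).sum() < 2:
        return {name: dim.sample(rng) for name, dim in space.items()}
    config = {}
    for name, dim in space.items():
        vals = np.array([t.config[name] for t in history], dtype=float)
        config[name] = _parzen_sample_and_score(dim, vals[good_idx], vals[~good_idx], rng)
    return config


def tune(
    objective: Callable[[dict[str, float]], float],
    space: dict[str, Dimension] | None = None,
    n_trials: int = 100,
    seed: int = 0,
    gamma: float = 0.25,
    random_share: float = 0.25,
) -> tuple[dict[str, float], list[Trial]]:
    """Minimise ``objective`` over ``space``; return (best config, trace).

    ``objective`` maps a configuration dict to a loss.  The trace
    holds every trial in evaluation order.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    space = space or DEFAULT_SPACE
    rng = np.random.default_rng(seed)
    history: list[Trial] = []
    for _ in range(n_trials):
        config = suggest(space, history, rng, gamma=gamma, random_share=random_share)
        loss = float(objective(config))
        if not np.isfinite(loss):
            raise FloatingPointError(f"objective returned non-finite loss for {config}")
        history.append(Trial(config, loss))
    best = min(history, key=lambda t: t.loss)
    return dict(best.config), history
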