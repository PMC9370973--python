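"""Sequential model-based hyperparameter search.

A small Bayesian optimizer over mixed search spaces: dimensions are encoded
into the unit cube (log-scaling for log-uniform dimensions, one-hot for
categoricals), a Gaussian-process surrogate with a Matern kernel is fitted to
the observed losses, and the next configuration is the expected-improvement
maximizer over a random candidate pool.  ``method="random"`` falls back to
pure random search with the same budget and seeding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import Matern

from ppgqc.exceptions import ParameterError


@dataclass(frozen=True)
class Real:
    name: str
    low: float
    high: float
    log: bool = False

    def sample(self, rng: np.random.Generator):
        if self.log:
            return float(np.exp(rng.uniform(np.log(self.low), np.log(self.high))))
        return float(rng.uniform(self.low, self.high))

    def encode(self, value: float) -> list[float]:
        if self.log:
            return [
                (np.log(value) - np.log(self.low)) / (np.log(self.high) - np.log(self.low))
            ]
        return [(value - self.low) / (self.high - self.low)]

    @property
    def width(self) -> int:
        return 1


@dataclass(frozen=True)
class Integer:
    name: str
    low: int
    high: int
    log: bool = False

    def sample(self, rng: np.random.Generator):
        if self.log:
            return int(round(np.exp(rng.uniform(np.log(self.low), np.log(self.high)))))
        return int(rng.integers(self.low, self.high + 1))

    def encode(self, value: int) -> list[float]:
        if self.log:
            return [
                (np.log(value) - np.log(self.low)) / (np.log(self.high) - np.log(self.low))
            ]
        return [(value - self.low) / max(self.high - self.low, 1)]

    @property
    def width(self) -> int:
        return 1


@dataclass(frozen=True)
class Categorical:
    name: str
    choices: tuple

    def sample(self, rng: np.random.Generator):
        return self.choices[int(rng.integers(len(self.choices)))]

    def encode(self, value) -> list[float]:
        out = [0.0] * len(self.choices)
        out[self.choices.index(value)] = 1.0
        return out

    @property
    def width(self) -> int:
        return len(self.choices)


def _encode_params(space, params: dict) -> np.ndarray:
    vec: list[float] = []
    for dim in space:
        vec.extend(dim.encode(params[dim.name]))
    return np.asarray(vec)


def _sample_params(space, rng: np.random.Generator) -> dict:
    return {dim.name: dim.sample(rng) for dim in space}


def _expected_improvement(mu: np.ndarray, sd: np.ndarray, best: float) -> np.ndarray:
    sd = np.maximum(sd, 1e-12)
    z = (best - mu) / sd
    return (best - mu) * stats.norm.cdf(z) + sd * stats.norm.pdf(z)


def minimize(
    objective,
    space,
    n_iter: int = 30,
    seed: int = 0,
    method: str = "smbo",
    n_initial: int | None = None,
    candidate_pool: int = 256,
) -> tuple[dict, float, list[tuple[dict, float]]]:
    """Minimize ``objective(params)`` over ``space`` with ``n_iter``
    sequential evaluations; returns (best params, best loss, history)."""
    if n_iter < 1:
        raise ParameterError("n_iter must be >= 1")
    if method not in ("smbo", "random"):
        raise ParameterError(f"unknown search method {method!r}")
    rng = np.random.default_rng(seed)
    if n_initial is None:
        n_initial = max(min(n_iter // 3, 10), min(5, n_iter))
    history: list[tuple[dict, float]] = []
    X_obs: list[np.ndarray] = []
    y_obs: list[float] = []

    for it in range(n_iter):
        if method == "random" or it < n_initial:
            params = _sample_params(space, rng)
        else:
            import warnings

            gp = GaussianProcessRegressor(
                kernel=Matern(nu=2.5, length_scale_bounds=(1e-2, 1e2)),
                alpha=1e-6,
                normalize_y=True,
                random_state=int(rng.integers(2**31 - 1)),
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                gp.fit(np.vstack(X_obs), np.asarray(y_obs))
            candidates = [_sample_params(space, rng) for _ in range(candidate_pool)]
            enc = np.vstack([_encode_params(space, c) for c in candidates])
            mu, sd = gp.predict(enc, return_std=True)
            ei = _expected_improvement(mu, sd, min(y_obs))
            params = candidates[int(np.argmax(ei))]
        loss = float(objective(params))
        history.append((params, loss))
        X_obs.append(_encode_params(space, params))
        y_obs.append(loss)

    best_idx = int(np.argmin(y_obs))
    return history[best_idx][0], history[best_idx][1], history
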