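"""Gaussian-process Bayesian optimization over a box hyperparameter space.

Sequential model-based optimization: after an initial Latin-hypercube-free
random design, a Gaussian process with a Matern kernel is fitted to the
observed (configuration, objective) pairs and the next configuration
maximizes expected improvement over a random candidate pool.  Small and
dependency-free beyond scikit-learn; adequate for the low-dimensional tree
hyperparameter spaces used here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np
from scipy.stats import norm
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import Matern

__all__ = ["ParamRange", "bayes_optimize"]


@dataclass(frozen=True)
class ParamRange:
    """Closed range for one hyperparameter.

    ``kind``: ``float``, ``int`` or ``logfloat`` (sampled and modeled on a
    log10 scale).
    """

    low: float
    high: float
    kind: str = "float"

    def __post_init__(self):
        if self.kind not in ("float", "int", "logfloat"):
            raise ValueError(f"unknown kind {self.kind!r}")
        if not self.low < self.high:
            raise ValueError("need low < high")
        if self.kind == "logfloat" and self.low <= 0:
            raise ValueError("logfloat range must be positive")

    def to_unit(self, value: float) -> float:
        if self.kind == "logfloat":
            return (np.log10(value) - np.log10(self.low)) / (
                np.log10(self.high) - np.log10(self.low)
            )
        return (value - self.low) / (self.high - self.low)

    def from_unit(self, u: float) -> float:
        u = float(np.clip(u, 0.0, 1.0))
        if self.kind == "logfloat":
            return float(10 ** (np.log10(self.low) + u * (np.log10(self.high) - np.log10(self.low))))
        value = self.low + u * (self.high - self.low)
        if self.kind == "int":
            return int(round(value))
        return float(value)


def bayes_optimize(
    objective: Callable[[dict], float],
    space: Mapping[str, ParamRange],
    n_iter: int,
    seed: int = 0,
    n_init: int | None = None,
    n_candidates: int = 256,
) -> tuple[dict, float, list[tuple[dict, float]]]:
    """Maximize ``objective`` over ``space`` in ``n_iter`` evaluations.

    Returns ``(best_params, best_value, history)``.  Every proposal lies
    inside the declared ranges; the run is reproducible given ``seed``.
    """
    if not space:
        raise ValueError("empty hyperparameter space")
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    names = list(space)
    ranges = [space[n] for n in names]
    rng = np.random.default_rng(seed)
    n_init = n_init if n_init is not None else max(3, min(n_iter // 2, 8))
    n_init = min(n_init, n_iter)

    def decode(u: np.ndarray) -> dict:
        return {n: r.from_unit(v) for n, r, v in zip(names, ranges, u)}

    history: list[tuple[dict, float]] = []
    X_unit: list[np.ndarray] = []
    y: list[float] = []
    for i in range(n_iter):
        if i < n_init:
            u = rng.random(len(names))
        else:
            kernel = Matern(nu=2.5, length_scale=np.full(len(names), 0.3),
                            length_scale_bounds=(1e-2, 1e2))
            gp = GaussianProcessRegressor(
                kernel=kernel, alpha=1e-6, normalize_y=True,
                n_restarts_optimizer=1, random_state=int(rng.integers(2**31)),
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                gp.fit(np.vstack(X_unit), np.asarray(y))
            cand = rng.random((n_candidates, len(names)))
            mu, sigma = gp.predict(cand, return_std=True)
            best = max(y)
            sigma = np.maximum(sigma, 1e-12)
            z = (mu - best) / sigma
            ei = (mu - best) * norm.cdf(z) + sigma * norm.pdf(z)
            u = cand[int(np.argmax(ei))]
        params = decode(u)
        value = float(objective(params))
        # re-encode (int rounding snaps to the grid) for the GP
        X_unit.append(np.array([r.to_unit(params[n]) for n, r in zip(names, ranges)]))
        y.append(value)
        history.append((params, value))
    best_idx = int(np.argmax(y))
    return history[best_idx][0], y[best_idx], history
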