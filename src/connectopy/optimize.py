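"""Gaussian-process Bayesian optimization for embedding hyper-parameters.

A small sequential model-based optimizer: seeded random starts, then a
Matern-5/2 GP surrogate with expected-improvement acquisition maximized
over random candidates.  Trials whose objective is ``-inf`` (e.g. a
parameter value yielding a disconnected neighbourhood graph) are kept in
the trace but imputed below the worst finite score when fitting the
surrogate, so the search moves away from invalid regions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm
from sklearn.exceptions import ConvergenceWarning
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern, WhiteKernel

__all__ = ["Real", "Integer", "SearchSpace", "Trial", "OptimizeResult", "bayes_maximize"]


@dataclass(frozen=True)
class Real:
    name: str
    low: float
    high: float
    log: bool = False


@dataclass(frozen=True)
class Integer:
    name: str
    low: int
    high: int
    log: bool = False


class SearchSpace:
    """Maps between parameter dicts and the unit hypercube."""

    def __init__(self, dimensions: list):
        if not dimensions:
            raise ValueError("search space must contain at least one dimension")
        for dim in dimensions:
            if dim.low >= dim.high:
                raise ValueError(f"dimension {dim.name!r} has empty range")
            if dim.log and dim.low <= 0:
                raise ValueError(f"log dimension {dim.name!r} requires low > 0")
        self.dimensions = list(dimensions)

    @property
    def n_dims(self) -> int:
        return len(self.dimensions)

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.uniform(size=(n, self.n_dims))

    def to_params(self, u: np.ndarray) -> dict:
        params = {}
        for ui, dim in zip(u, self.dimensions):
            if dim.log:
                val = 10 ** (
                    np.log10(dim.low) + ui * (np.log10(dim.high) - np.log10(dim.low))
                )
            else:
                val = dim.low + ui * (dim.high - dim.low)
            if isinstance(dim, Integer):
                val = int(np.clip(round(val), dim.low, dim.high))
            else:
                val = float(val)
            params[dim.name] = val
        return params


@dataclass
class Trial:
    params: dict
    score: float
    valid: bool


@dataclass
class OptimizeResult:
    best_params: dict
    best_score: float
    trials: list[Trial] = field(default_factory=list)


def _expected_improvement(mu, sigma, best):
    sigma = np.maximum(sigma, 1e-12)
    z = (mu - best) / sigma
    return (mu - best) * norm.cdf(z) + sigma * norm.pdf(z)


def bayes_maximize(
    objective,
    space: SearchSpace,
    n_calls: int,
    n_random_starts: int,
    seed: int = 0,
    n_candidates: int = 256,
) -> OptimizeResult:
    """Maximize ``objective(params_dict) -> float`` over ``space``.

    ``-inf`` scores mark invalid trials.  Raises if every trial is invalid.
    """
    if n_calls < 1:
        raise ValueError("n_calls must be >= 1")
    n_random_starts = min(max(1, n_random_starts), n_calls)
    rng = np.random.default_rng(seed)
    u_seen: list[np.ndarray] = []
    scores: list[float] = []
    trials: list[Trial] = []
    cache: dict[tuple, float] = {}

    def evaluate(u):
        params = space.to_params(u)
        key = tuple(sorted(params.items()))
        if key in cache:
            score = cache[key]
        else:
            score = float(objective(params))
            cache[key] = score
        u_seen.append(u)
        scores.append(score)
        trials.append(Trial(params, score, bool(np.isfinite(score))))

    for u in space.sample(rng, n_random_starts):
        evaluate(u)

    kernel = ConstantKernel(1.0) * Matern(
        length_scale=np.full(space.n_dims, 0.25), nu=2.5
    ) + WhiteKernel(noise_level=1e-6, noise_level_bounds=(1e-10, 1e-1))

    while len(trials) < n_calls:
        y = np.asarray(scores)
        finite = np.isfinite(y)
        if not finite.any():
            # keep sampling at random until something is valid
            evaluate(space.sample(rng, 1)[0])
            continue
        # impute invalid trials just below the worst valid score
        y_fit = y.copy()
        spread = max(y[finite].max() - y[finite].min(), 1e-3)
        y_fit[~finite] = y[finite].min() - spread
        gp = GaussianProcessRegressor(
            kernel=kernel,
            normalize_y=True,
            alpha=1e-10,
            n_restarts_optimizer=1,
            random_state=int(rng.integers(2**31 - 1)),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            gp.fit(np.vstack(u_seen), y_fit)
        cand = space.sample(rng, n_candidates)
        # local perturbations around the incumbent sharpen the search
        best_u = u_seen[int(np.argmax(y_fit))]
        local = np.clip(
            best_u + 0.05 * rng.standard_normal((n_candidates // 4, space.n_dims)),
            0.0,
            1.0,
        )
        cand = np.vstack([cand, local])
        mu, sigma = gp.predict(cand, return_std=True)
        ei = _expected_improvement(mu, sigma, y_fit.max())
        evaluate(cand[int(np.argmax(ei))])

    y = np.asarray(scores)
    if not np.isfinite(y).any():
        raise RuntimeError("all optimizer trials were invalid")
    best = int(np.nanargmax(np.where(np.isfinite(y), y, -np.inf)))
    return OptimizeResult(trials[best].params, float(y[best]), trials)
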