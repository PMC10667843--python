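"""Sequential model-based (Bayesian) hyperparameter optimization.

A Gaussian-process surrogate (Matérn 5/2 + white noise) is fit to the
observed (configuration, validation score) pairs in the unit hypercube;
each round evaluates the configuration that maximizes expected improvement
over a random candidate set.  Log-scaled and integer dimensions are handled
in the encoding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern, WhiteKernel


@dataclass(frozen=True)
class Dim:
    low: float
    high: float
    log: bool = False
    integer: bool = False

    def decode(self, u: float):
        if self.log:
            v = self.low * (self.high / self.low) ** u
        else:
            v = self.low + (self.high - self.low) * u
        return int(round(v)) if self.integer else float(v)


#: bounds used when searching decoder hyperparameters
DEFAULT_SEARCH_SPACE: dict[str, Dim] = {
    "hidden": Dim(16, 256, log=True, integer=True),
    "dropout": Dim(0.0, 0.5),
    "lr": Dim(1e-4, 1e-2, log=True),
    "batch_size": Dim(16, 128, log=True, integer=True),
}

#: reduced bounds for desk-scale runs (smaller nets, same dimensions)
SMALL_SEARCH_SPACE: dict[str, Dim] = {
    "hidden": Dim(16, 96, log=True, integer=True),
    "dropout": Dim(0.0, 0.4),
    "lr": Dim(5e-4, 1e-2, log=True),
    "batch_size": Dim(32, 128, log=True, integer=True),
}


@dataclass
class BayesOptResult:
    best_config: dict
    best_value: float
    trace: list = field(default_factory=list)  # (config, value) per round

    def best_curve(self) -> np.ndarray:
        """Best value observed up to each round (monotone non-decreasing)."""
        return np.maximum.accumulate([v for _, v in self.trace])


def _decode(space: dict[str, Dim], u: np.ndarray) -> dict:
    return {name: dim.decode(ui) for (name, dim), ui in zip(space.items(), u)}


def bayesian_optimize(
    objective: Callable[[dict], float],
    space: dict[str, Dim],
    rounds: int = 60,
    seed: int = 0,
    n_init: int = 5,
    n_candidates: int = 256,
    xi: float = 0.01,
) -> BayesOptResult:
    """Maximize ``objective`` over ``space`` with GP expected improvement.

    The first ``min(n_init, rounds)`` rounds are space-filling random draws;
    subsequent rounds fit the GP to all observations and evaluate the
    expected-improvement maximizer over a fresh random candidate set.
    """
    if rounds < 1:
        raise ValueError("rounds must be >= 1")
    rng = np.random.default_rng(seed)
    d = len(space)
    U: list[np.ndarray] = []
    ys: list[float] = []
    trace: list[tuple[dict, float]] = []
    for r in range(rounds):
        if r < min(n_init, rounds) or len(set(np.round(ys, 12))) < 2:
            u = rng.random(d)
        else:
            kernel = (
                ConstantKernel(1.0, (1e-3, 1e3))
                * Matern(length_scale=np.full(d, 0.3), length_scale_bounds=(1e-2, 1e2), nu=2.5)
                + WhiteKernel(1e-4, (1e-8, 1e1))
            )
            import warnings as _w

            gp = GaussianProcessRegressor(kernel=kernel, normalize_y=True, random_state=int(rng.integers(2**31)))
            with _w.catch_warnings():
                _w.simplefilter("ignore", ConvergenceWarning)
                gp.fit(np.vstack(U), np.asarray(ys))
            cand = rng.random((n_candidates, d))
            mu, sd = gp.predict(cand, return_std=True)
            best = max(ys)
            sd = np.maximum(sd, 1e-9)
            z = (mu - best - xi) / sd
            ei = (mu - best - xi) * stats.norm.cdf(z) + sd * stats.norm.pdf(z)
            u = cand[int(np.argmax(ei))]
        cfg = _decode(space, u)
        val = float(objective(cfg))
        U.append(u)
        ys.append(val)
        trace.append((cfg, val))
    i_best = int(np.argmax(ys))
    return BayesOptResult(best_config=trace[i_best][0], best_value=ys[i_best], trace=trace)
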