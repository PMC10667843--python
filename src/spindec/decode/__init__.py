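"""Movement decoding: recurrent and linear decoders, splits, search, R²."""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import stats as _stats

from spindec.decode.bayesopt import (
    DEFAULT_SEARCH_SPACE,
    SMALL_SEARCH_SPACE,
    BayesOptResult,
    Dim,
    bayesian_optimize,
)
from spindec.decode.decoder import (
    DecodeResult,
    DecoderConfig,
    SplitSpec,
    evaluate_r2,
    split_session,
    train_decoder,
)

__all__ = [
    "DEFAULT_SEARCH_SPACE",
    "SMALL_SEARCH_SPACE",
    "BayesOptResult",
    "DecodeResult",
    "DecoderConfig",
    "Dim",
    "SplitSpec",
    "anova_oneway",
    "bayesian_optimize",
    "evaluate_r2",
    "optimize_decoder",
    "split_session",
    "train_decoder",
]


def optimize_decoder(
    X: np.ndarray,
    Y: np.ndarray,
    rounds: int = 60,
    repeats: int = 5,
    seed: int = 0,
    space: dict[str, Dim] | None = None,
    base_config: DecoderConfig | None = None,
    split: SplitSpec | None = None,
) -> list[DecodeResult]:
    """Hyperparameter search + final evaluation, repeated with fresh seeds.

    Each repeat runs a Bayesian optimization over the search space, scoring
    candidate configurations by mean validation R²; the best configuration
    is then refit and evaluated once on the held-out test block.  Test data
    never influence selection.
    """
    base = base_config or DecoderConfig()
    space = space or DEFAULT_SEARCH_SPACE
    tr, va, te = split_session(len(X), split)
    results: list[DecodeResult] = []
    for rep in range(repeats):
        rep_seed = (seed + 1000003 * rep) % (2**31)

        def objective(hp: dict, _seed=rep_seed) -> float:
            cfg = dataclasses.replace(base, seed=_seed, **hp)
            model = train_decoder(X, Y, cfg, tr, va)
            r2 = evaluate_r2(model.predict(X[va]), Y[va])
            return float(np.nanmean(r2))

        opt = bayesian_optimize(objective, space, rounds=rounds, seed=rep_seed)
        best_cfg = dataclasses.replace(base, seed=rep_seed, **opt.best_config)
        model = train_decoder(X, Y, best_cfg, tr, va)
        pred = model.predict(X[te])
        results.append(
            DecodeResult(
                r2_test=evaluate_r2(pred, Y[te]),
                r2_val=opt.best_value,
                predictions=pred,
                best_config=best_cfg,
                trace=opt.trace,
            )
        )
    return results


def anova_oneway(*groups) -> tuple[float, float]:
    """One-way ANOVA across groups of R² values; returns (F, p)."""
    f, p = _stats.f_oneway(*groups)
    return float(f), float(p)
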