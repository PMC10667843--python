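"""Kinematic decoders: the recurrent model, a ridge baseline, and R².

The decoder maps each frame's lookback tensor (26 bins x channels, treated
as a length-26 sequence, oldest bin first) to the frame's joint
coordinates.  Sessions are split into contiguous chronological blocks
(train:valid:test = 0.8:0.1:0.1); model selection sees only the validation
block, the test block is touched once for the reported R².
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import Ridge

from spindec.decode.nets import Adam, LSTMRegressor, clip_gradients


@dataclass
class SplitSpec:
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)
    scheme: str = "contiguous"

    def __post_init__(self) -> None:
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if self.scheme != "contiguous":
            raise ValueError("only contiguous splits are supported")


def split_session(
    n_frames: int, spec: SplitSpec | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Contiguous train/validation/test index blocks in chronological order."""
    spec = spec or SplitSpec()
    n_train = int(np.floor(spec.fractions[0] * n_frames))
    n_val = int(np.floor(spec.fractions[1] * n_frames))
    idx = np.arange(n_frames)
    return idx[:n_train], idx[n_train : n_train + n_val], idx[n_train + n_val :]


@dataclass
class DecoderConfig:
    architecture: str = "lstm"  # 'lstm' | 'ridge'
    hidden: int = 64
    dropout: float = 0.2
    lr: float = 3e-3
    epochs: int = 60
    batch_size: int = 64
    seed: int = 0
    patience: int = 8
    grad_clip: float = 5.0
    ridge_alpha: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.architecture not in ("lstm", "ridge"):
            raise ValueError("architecture must be 'lstm' or 'ridge'")


class _Standardizer:
    """Per-channel z-scoring of feature tensors, fit on the training block."""

    def fit(self, X: np.ndarray) -> "_Standardizer":
        self.mean_ = X.mean(axis=(0, 1), keepdims=True)
        sd = X.std(axis=(0, 1), keepdims=True)
        self.sd_ = np.where(sd > 0, sd, 1.0)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean_) / self.sd_


class FittedLSTM:
    def __init__(self, net: LSTMRegressor, scaler: _Standardizer, history: dict):
        self.net = net
        self.scaler = scaler
        self.history = history

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.net.predict(self.scaler.transform(np.asarray(X, dtype=float)))


class FittedRidge:
    def __init__(self, model: Ridge, scaler: _Standardizer):
        self.model = model
        self.scaler = scaler
        self.history: dict = {}

    def predict(self, X: np.ndarray) -> np.ndarray:
        Xs = self.scaler.transform(np.asarray(X, dtype=float))
        return self.model.predict(Xs.reshape(len(Xs), -1))


def train_decoder(
    X: np.ndarray,
    Y: np.ndarray,
    config: DecoderConfig,
    train_idx: np.ndarray,
    val_idx: np.ndarray | None = None,
):
    """Fit a decoder on the training block; early-stop on validation MSE.

    ``X`` is frames x bins x channels (sequence runs oldest-first into the
    recurrent layers), ``Y`` frames x targets (normalized coordinates).
    Training is deterministic under ``config.seed``.
    """
    X = np.asarray(X, dtype=float)
    Y = np.atleast_2d(np.asarray(Y, dtype=float).T).T
    scaler = _Standardizer().fit(X[train_idx])
    if config.architecture == "ridge":
        Xs = scaler.transform(X[train_idx]).reshape(len(train_idx), -1)
        model = Ridge(alpha=config.ridge_alpha)
        model.fit(Xs, Y[train_idx])
        return FittedRidge(model, scaler)

    rng = np.random.default_rng(config.seed)
    net = LSTMRegressor(
        d_in=X.shape[2],
        d_hidden=config.hidden,
        d_out=Y.shape[1],
        dropout=config.dropout,
        seed=int(rng.integers(2**31)),
    )
    Xtr = scaler.transform(X[train_idx])
    Ytr = Y[train_idx]
    Xva = scaler.transform(X[val_idx]) if val_idx is not None and len(val_idx) else None
    Yva = Y[val_idx] if Xva is not None else None

    params = net.get_params()
    opt = Adam(params, lr=config.lr)
    n = len(Xtr)
    init_loss = float(np.mean((net.predict(Xtr) - Ytr) ** 2))
    best_val = np.inf
    best_params = {k: v.copy() for k, v in params.items()}
    stall = 0
    history: dict = {"train_loss": [], "val_loss": []}
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        ep_loss = 0.0
        for i in range(0, n, config.batch_size):
            sel = order[i : i + config.batch_size]
            pred, cache = net.forward(Xtr[sel], training=True)
            err = pred - Ytr[sel]
            loss = float(np.mean(err**2))
            ep_loss += loss * len(sel)
            dy = 2.0 * err / err.size
            grads = net.backward(dy, cache)
            clip_gradients(grads, config.grad_clip)
            opt.step(params, grads)
        ep_loss /= n
        # anything orders of magnitude above the untrained loss is a
        # runaway, even though bounded activations keep it finite
        exploded = ep_loss > 1e6 * max(init_loss, 1e-12)
        if not np.isfinite(ep_loss) or exploded:
            raise RuntimeError(
                f"training diverged at epoch {epoch}: loss={ep_loss}; "
                f"history={history['train_loss']}"
            )
        history["train_loss"].append(ep_loss)
        if Xva is not None:
            val_loss = float(np.mean((net.predict(Xva) - Yva) ** 2))
            history["val_loss"].append(val_loss)
            if val_loss < best_val - 1e-7:
                best_val = val_loss
                best_params = {k: v.copy() for k, v in params.items()}
                stall = 0
            else:
                stall += 1
                if stall >= config.patience:
                    break
    if Xva is not None:
        net.set_params(best_params)
    return FittedLSTM(net, scaler, history)


def evaluate_r2(pred: np.ndarray, actual: np.ndarray) -> np.ndarray:
    """Coefficient of determination per target column.

    R² = 1 - SS_res / SS_tot with SS_tot about the evaluation-set mean.
    Zero-variance targets yield NaN with a warning.
    """
    p = np.atleast_2d(np.asarray(pred, dtype=float).T).T
    a = np.atleast_2d(np.asarray(actual, dtype=float).T).T
    if p.shape != a.shape:
        raise ValueError("pred and actual shapes differ")
    ss_res = np.sum((a - p) ** 2, axis=0)
    ss_tot = np.sum((a - a.mean(axis=0)) ** 2, axis=0)
    out = np.full(a.shape[1], np.nan)
    nz = ss_tot > 0
    out[nz] = 1.0 - ss_res[nz] / ss_tot[nz]
    if not nz.all():
        warnings.warn("zero-variance target column(s); R^2 undefined -> NaN")
    return out


@dataclass
class DecodeResult:
    r2_test: np.ndarray  # per target
    r2_val: float
    predictions: np.ndarray
    best_config: DecoderConfig
    trace: list = field(default_factory=list)
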