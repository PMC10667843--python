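"""A small recurrent regression network in pure NumPy.

Architecture: two LSTM layers with layer normalization and dropout between
them, a linear read-out from the last hidden state.  Gradients are computed
by hand (backpropagation through time) and optimized with Adam.  CPU-sized
problems only: sequences of a few dozen steps, hidden sizes up to a few
hundred.
"""

from __future__ import annotations

import numpy as np


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))


class LSTMLayer:
    """Single LSTM layer over [batch, time, features] input."""

    def __init__(self, d_in: int, d_hidden: int, rng: np.random.Generator):
        s = 1.0 / np.sqrt(d_hidden)
        self.Wx = rng.uniform(-s, s, size=(d_in, 4 * d_hidden))
        self.Wh = rng.uniform(-s, s, size=(d_hidden, 4 * d_hidden))
        self.b = np.zeros(4 * d_hidden)
        self.b[d_hidden : 2 * d_hidden] = 1.0  # forget-gate bias
        self.H = d_hidden

    def params(self) -> dict[str, np.ndarray]:
        return {"Wx": self.Wx, "Wh": self.Wh, "b": self.b}

    def forward(self, x: np.ndarray):
        B, T, _ = x.shape
        H = self.H
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        hs = np.empty((B, T, H))
        cache = []
        for t in range(T):
            z = x[:, t] @ self.Wx + h @ self.Wh + self.b
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H : 2 * H])
            g = np.tanh(z[:, 2 * H : 3 * H])
            o = _sigmoid(z[:, 3 * H :])
            c_prev = c
            c = f * c_prev + i * g
            tc = np.tanh(c)
            h_prev = h
            h = o * tc
            hs[:, t] = h
            cache.append((x[:, t], h_prev, c_prev, i, f, g, o, c, tc))
        return hs, cache

    def backward(self, dh_seq: np.ndarray, cache) -> tuple[np.ndarray, dict[str, np.ndarray]]:
        B, T, H = dh_seq.shape
        dWx = np.zeros_like(self.Wx)
        dWh = np.zeros_like(self.Wh)
        db = np.zeros_like(self.b)
        dx_seq = np.empty((B, T, self.Wx.shape[0]))
        dh_next = np.zeros((B, H))
        dc_next = np.zeros((B, H))
        for t in range(T - 1, -1, -1):
            x_t, h_prev, c_prev, i, f, g, o, c, tc = cache[t]
            dh = dh_seq[:, t] + dh_next
            dc = dc_next + dh * o * (1.0 - tc**2)
            dz = np.concatenate(
                [
                    dc * g * i * (1.0 - i),
                    dc * c_prev * f * (1.0 - f),
                    dc * i * (1.0 - g**2),
                    dh * tc * o * (1.0 - o),
                ],
                axis=1,
            )
            dWx += x_t.T @ dz
            dWh += h_prev.T @ dz
            db += dz.sum(axis=0)
            dx_seq[:, t] = dz @ self.Wx.T
            dh_next = dz @ self.Wh.T
            dc_next = dc * f
        return dx_seq, {"Wx": dWx, "Wh": dWh, "b": db}


class LayerNorm:
    """Layer normalization over the feature dimension."""

    def __init__(self, d: int, eps: float = 1e-5):
        self.gamma = np.ones(d)
        self.beta = np.zeros(d)
        self.eps = eps

    def params(self) -> dict[str, np.ndarray]:
        return {"gamma": self.gamma, "beta": self.beta}

    def forward(self, x: np.ndarray):
        mu = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        return xhat * self.gamma + self.beta, (xhat, inv)

    def backward(self, dy: np.ndarray, cache) -> tuple[np.ndarray, dict[str, np.ndarray]]:
        xhat, inv = cache
        dgamma = (dy * xhat).sum(axis=tuple(range(dy.ndim - 1)))
        dbeta = dy.sum(axis=tuple(range(dy.ndim - 1)))
        dxhat = dy * self.gamma
        m1 = dxhat.mean(axis=-1, keepdims=True)
        m2 = (dxhat * xhat).mean(axis=-1, keepdims=True)
        dx = inv * (dxhat - m1 - xhat * m2)
        return dx, {"gamma": dgamma, "beta": dbeta}


class LSTMRegressor:
    """Two-layer LSTM -> layer norm -> dropout -> LSTM -> linear read-out."""

    def __init__(
        self,
        d_in: int,
        d_hidden: int,
        d_out: int,
        dropout: float = 0.0,
        seed: int = 0,
    ):
        if not 0.0 <= dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        rng = np.random.default_rng(seed)
        self.lstm1 = LSTMLayer(d_in, d_hidden, rng)
        self.ln = LayerNorm(d_hidden)
        self.lstm2 = LSTMLayer(d_hidden, d_hidden, rng)
        s = 1.0 / np.sqrt(d_hidden)
        self.Wo = rng.uniform(-s, s, size=(d_hidden, d_out))
        self.bo = np.zeros(d_out)
        self.dropout = dropout
        self._rng = rng

    # parameter plumbing -------------------------------------------------
    def _param_groups(self):
        return [
            ("lstm1", self.lstm1.params()),
            ("ln", self.ln.params()),
            ("lstm2", self.lstm2.params()),
            ("head", {"Wo": self.Wo, "bo": self.bo}),
        ]

    def get_params(self) -> dict[str, np.ndarray]:
        return {f"{g}.{k}": v for g, ps in self._param_groups() for k, v in ps.items()}

    def set_params(self, flat: dict[str, np.ndarray]) -> None:
        for g, ps in self._param_groups():
            for k, v in ps.items():
                v[...] = flat[f"{g}.{k}"]

    # forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray, training: bool = False):
        h1, c1 = self.lstm1.forward(x)
        h1n, cln = self.ln.forward(h1)
        if training and self.dropout > 0.0:
            keep = (self._rng.random(h1n.shape) >= self.dropout) / (1.0 - self.dropout)
        else:
            keep = None
        h1d = h1n * keep if keep is not None else h1n
        h2, c2 = self.lstm2.forward(h1d)
        h_last = h2[:, -1]
        y = h_last @ self.Wo + self.bo
        return y, (x, c1, cln, keep, c2, h_last)

    def backward(self, dy: np.ndarray, cache) -> dict[str, np.ndarray]:
        x, c1, cln, keep, c2, h_last = cache
        grads: dict[str, np.ndarray] = {}
        grads["head.Wo"] = h_last.T @ dy
        grads["head.bo"] = dy.sum(axis=0)
        B, T = x.shape[0], x.shape[1]
        dh2 = np.zeros((B, T, self.lstm2.H))
        dh2[:, -1] = dy @ self.Wo.T
        dh1d, g2 = self.lstm2.backward(dh2, c2)
        for k, v in g2.items():
            grads[f"lstm2.{k}"] = v
        if keep is not None:
            dh1d = dh1d * keep
        dh1n, gln = self.ln.backward(dh1d, cln)
        for k, v in gln.items():
            grads[f"ln.{k}"] = v
        _, g1 = self.lstm1.backward(dh1n, c1)
        for k, v in g1.items():
            grads[f"lstm1.{k}"] = v
        return grads

    def predict(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        outs = []
        for i in range(0, len(x), batch_size):
            y, _ = self.forward(x[i : i + batch_size], training=False)
            outs.append(y)
        return np.concatenate(outs, axis=0)


class Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for k, p in params.items():
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def clip_gradients(grads: dict[str, np.ndarray], max_norm: float) -> None:
    total = np.sqrt(sum(float((g**2).sum()) for g in grads.values()))
    if total > max_norm > 0:
        scale = max_norm / total
        for g in grads.values():
            g *= scale
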