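"""Minimal neural-network layers with analytic backprop, on NumPy.

Everything runs in float64, channels-last: activations have shape
(batch, time, channels). Each layer owns its parameters and gradient
buffers; ``forward`` caches what ``backward`` needs. The layer set is
exactly what the next-base predictor requires — 1-D convolution, batch
normalization, max pooling, dropout, (bi)directional LSTM, dense — plus
an Adam optimizer. Gradients are verified against central finite
differences in the test suite.

Determinism: given identical parameters, inputs and dropout RNG state,
forward and backward are bit-reproducible (pure NumPy ops, no threading
nondeterminism at these sizes).
"""

from __future__ import annotations

import numpy as np


def _glorot(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Layer:
    """Base: parameter/gradient dicts keyed by local names."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def zero_grads(self) -> None:
        for k, v in self.params.items():
            self.grads[k] = np.zeros_like(v)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv1d(Layer):
    """Temporal convolution, channels-last: (B, L, C_in) -> (B, L_out, C_out).

    out[t] = sum_{k} W[k] . x[t*stride + k - pad] + b, zero-padded.
    """

    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int = 1,
                 pad: int | None = None, rng: np.random.Generator | None = None):
        super().__init__()
        if kernel < 1 or stride < 1:
            raise ValueError("kernel and stride must be >= 1")
        self.c_in, self.c_out, self.k, self.stride = c_in, c_out, kernel, stride
        self.pad = (kernel - 1) // 2 if pad is None else pad
        rng = rng or np.random.default_rng(0)
        self.params["W"] = _glorot(rng, (kernel * c_in, c_out), kernel * c_in, c_out)
        self.params["b"] = np.zeros(c_out)
        self.zero_grads()

    def out_len(self, length: int) -> int:
        return (length + 2 * self.pad - self.k) // self.stride + 1

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        B, L, _ = x.shape
        L_out = self.out_len(L)
        if L_out < 1:
            raise ValueError(f"input length {L} too short for kernel {self.k}")
        xp = np.pad(x, ((0, 0), (self.pad, self.pad), (0, 0)))
        idx = np.arange(L_out)[:, None] * self.stride + np.arange(self.k)[None, :]
        cols = xp[:, idx, :].reshape(B, L_out, self.k * self.c_in)
        self._cache = (x.shape, idx, cols)
        return cols @ self.params["W"] + self.params["b"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        (B, L, C), idx, cols = self._cache
        self.grads["W"] += np.einsum("blk,blo->ko", cols, dout)
        self.grads["b"] += dout.sum(axis=(0, 1))
        dcols = (dout @ self.params["W"].T).reshape(B, -1, self.k, self.c_in)
        dxp = np.zeros((B, L + 2 * self.pad, C))
        for k in range(self.k):  # idx[:, k] strictly increasing => no collisions
            dxp[:, idx[:, k], :] += dcols[:, :, k, :]
        return dxp[:, self.pad : self.pad + L, :]


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class BatchNorm1d(Layer):
    """Per-channel normalization over (batch, time); running stats at eval."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.params["gamma"] = np.ones(channels)
        self.params["beta"] = np.zeros(channels)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.zero_grads()

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            mu = x.mean(axis=(0, 1))
            var = x.var(axis=(0, 1))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mu
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mu, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        self._cache = (xhat, inv, train, x.shape[0] * x.shape[1])
        return self.params["gamma"] * xhat + self.params["beta"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv, train, n = self._cache
        self.grads["gamma"] += (dout * xhat).sum(axis=(0, 1))
        self.grads["beta"] += dout.sum(axis=(0, 1))
        dxhat = dout * self.params["gamma"]
        if not train:
            return dxhat * inv
        return (inv / n) * (
            n * dxhat
            - dxhat.sum(axis=(0, 1))
            - xhat * (dxhat * xhat).sum(axis=(0, 1))
        )


class MaxPool1d(Layer):
    """Non-overlapping temporal max pool; trailing remainder is dropped."""

    def __init__(self, pool: int):
        super().__init__()
        if pool < 1:
            raise ValueError("pool must be >= 1")
        self.pool = pool

    def out_len(self, length: int) -> int:
        return length // self.pool

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        B, L, C = x.shape
        Lo = L // self.pool
        if Lo < 1:
            raise ValueError(f"pool {self.pool} larger than sequence length {L}")
        xr = x[:, : Lo * self.pool, :].reshape(B, Lo, self.pool, C)
        self._cache = (x.shape, np.argmax(xr, axis=2))
        return np.max(xr, axis=2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        (B, L, C), arg = self._cache
        Lo = dout.shape[1]
        dxr = np.zeros((B, Lo, self.pool, C))
        np.put_along_axis(dxr, arg[:, :, None, :], dout[:, :, None, :], axis=2)
        dx = np.zeros((B, L, C))
        dx[:, : Lo * self.pool, :] = dxr.reshape(B, Lo * self.pool, C)
        return dx


class Dropout(Layer):
    """Inverted dropout; identity at eval. The mask RNG is injected so the
    training loop controls all randomness."""

    def __init__(self, rate: float):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng: np.random.Generator | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        if self.rng is None:
            raise RuntimeError("Dropout.rng must be set before training forward")
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout if self._mask is None else dout * self._mask


class _LSTMDirection(Layer):
    """A single-direction LSTM scan. Gate order: input, forget, cell, output.

    Forget-gate bias starts at 1 (standard trick for gradient flow).
    """

    def __init__(self, d_in: int, hidden: int, reverse: bool,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.d_in, self.h, self.reverse = d_in, hidden, reverse
        rng = rng or np.random.default_rng(0)
        self.params["Wx"] = _glorot(rng, (d_in, 4 * hidden), d_in, hidden)
        self.params["Wh"] = _glorot(rng, (hidden, 4 * hidden), hidden, hidden)
        b = np.zeros(4 * hidden)
        b[hidden : 2 * hidden] = 1.0
        self.params["b"] = b
        self.zero_grads()

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if self.reverse:
            x = x[:, ::-1, :]
        B, T, _ = x.shape
        H = self.h
        Wx, Wh, b = self.params["Wx"], self.params["Wh"], self.params["b"]
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        hs = np.zeros((B, T, H))
        cache = []
        xg = x @ Wx + b  # precompute input contributions for all steps
        for t in range(T):
            gates = xg[:, t, :] + h @ Wh
            i = _sigmoid(gates[:, :H])
            f = _sigmoid(gates[:, H : 2 * H])
            g = np.tanh(gates[:, 2 * H : 3 * H])
            o = _sigmoid(gates[:, 3 * H :])
            c_new = f * c + i * g
            tc = np.tanh(c_new)
            h_new = o * tc
            cache.append((h, c, i, f, g, o, tc))
            h, c = h_new, c_new
            hs[:, t, :] = h
        self._cache = (x, hs, cache)
        return hs[:, ::-1, :] if self.reverse else hs

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self.reverse:
            dout = dout[:, ::-1, :]
        x, hs, cache = self._cache
        B, T, _ = x.shape
        H = self.h
        Wx, Wh = self.params["Wx"], self.params["Wh"]
        dWx = np.zeros_like(Wx)
        dWh = np.zeros_like(Wh)
        db = np.zeros_like(self.params["b"])
        dx = np.zeros_like(x)
        dh_next = np.zeros((B, H))
        dc_next = np.zeros((B, H))
        for t in range(T - 1, -1, -1):
            h_prev, c_prev, i, f, g, o, tc = cache[t]
            dh = dout[:, t, :] + dh_next
            do = dh * tc
            dc = dh * o * (1 - tc * tc) + dc_next
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dc_next = dc * f
            dgates = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f), dg * (1 - g * g), do * o * (1 - o)],
                axis=1,
            )
            dWx += x[:, t, :].T @ dgates
            dWh += h_prev.T @ dgates
            db += dgates.sum(axis=0)
            dx[:, t, :] = dgates @ Wx.T
            dh_next = dgates @ Wh.T
        self.grads["Wx"] += dWx
        self.grads["Wh"] += dWh
        self.grads["b"] += db
        return dx[:, ::-1, :] if self.reverse else dx


class BiLSTM(Layer):
    """Bidirectional LSTM: forward and reverse scans, outputs concatenated.

    (B, T, D) -> (B, T, 2H); first H channels forward, last H backward.
    """

    def __init__(self, d_in: int, hidden: int, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.fwd = _LSTMDirection(d_in, hidden, reverse=False, rng=rng)
        self.bwd = _LSTMDirection(d_in, hidden, reverse=True, rng=rng)
        self.h = hidden
        for name, sub in (("fwd", self.fwd), ("bwd", self.bwd)):
            for k, v in sub.params.items():
                self.params[f"{name}_{k}"] = v
        self.zero_grads()

    def zero_grads(self) -> None:
        super().zero_grads()
        for name, sub in (("fwd", self.fwd), ("bwd", self.bwd)):
            sub.zero_grads()
            for k in sub.params:
                self.grads[f"{name}_{k}"] = sub.grads[k]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return np.concatenate(
            [self.fwd.forward(x, train), self.bwd.forward(x, train)], axis=2
        )

    def backward(self, dout: np.ndarray) -> np.ndarray:
        H = self.h
        dx = self.fwd.backward(dout[:, :, :H])
        dx += self.bwd.backward(dout[:, :, H:])
        for name, sub in (("fwd", self.fwd), ("bwd", self.bwd)):
            for k in sub.params:
                self.grads[f"{name}_{k}"] = sub.grads[k]
        return dx


class GlobalMaxPool(Layer):
    """Max over the full time axis: (B, T, C) -> (B, C)."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._cache = (x.shape, np.argmax(x, axis=1))
        return np.max(x, axis=1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        shape, arg = self._cache
        dx = np.zeros(shape)
        np.put_along_axis(dx, arg[:, None, :], dout[:, None, :], axis=1)
        return dx


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.params["W"] = _glorot(rng, (d_in, d_out), d_in, d_out)
        self.params["b"] = np.zeros(d_out)
        self.zero_grads()

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads["W"] += self._x.T @ dout
        self.grads["b"] += dout.sum(axis=0)
        return dout @ self.params["W"].T


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_xent(logits: np.ndarray, targets: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over the batch and its gradient w.r.t. logits.

    ``targets`` holds integer class indices.
    """
    p = softmax(logits)
    n = logits.shape[0]
    loss = -np.log(np.maximum(p[np.arange(n), targets], 1e-300)).mean()
    dlogits = p.copy()
    dlogits[np.arange(n), targets] -= 1.0
    return float(loss), dlogits / n


class Adam:
    """Adam over a flat {name: array} parameter dict."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        bc1 = 1 - self.b1 ** self.t
        bc2 = 1 - self.b2 ** self.t
        for k, p in self.params.items():
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            p -= self.lr * (self.m[k] / bc1) / (np.sqrt(self.v[k] / bc2) + self.eps)
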