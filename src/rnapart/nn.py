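"""Minimal NumPy neural-network layers for per-position sequence labeling.

Every layer implements ``forward(x)`` / ``backward(dy)`` with caches on
the instance, and exposes trainable arrays in ``params`` with matching
``grads``.  Activations flow as ``(batch, length, features)`` float64
arrays.  Layers that depend on per-window validity masks (masking
multiplications, batch normalization statistics) read ``self.mask``
(shape (batch, length)); dropout layers read ``self.train`` and
``self.rng``, which the model sets before each pass.  Gradients are
exact — verified against central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer",
    "Conv1D",
    "Dense",
    "ReLU",
    "Dropout",
    "MaskMul",
    "BatchNorm",
    "BiLSTM",
    "ResNetLayer",
    "softmax",
    "softmax_cross_entropy",
    "Adam",
]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Layer:
    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self.mask: np.ndarray | None = None
        self.train: bool = False
        self.rng: np.random.Generator | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv1D(Layer):
    """1D convolution along the length axis, 'same' zero padding."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        super().__init__()
        if k < 1 or k % 2 == 0:
            raise ValueError("kernel size must be odd and positive")
        scale = np.sqrt(2.0 / (c_in * k))
        self.k = k
        self.params = {
            "W": rng.normal(0.0, scale, size=(c_out, c_in * k)),
            "b": np.zeros(c_out),
        }

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, L, F = x.shape
        k = self.k
        p = (k - 1) // 2
        xp = np.pad(x, ((0, 0), (p, k - 1 - p), (0, 0)))
        # (B, L, F, k) sliding view over the padded length axis
        col = np.lib.stride_tricks.sliding_window_view(xp, k, axis=1)
        col = np.ascontiguousarray(col).reshape(B * L, F * k)
        self._col = col
        self._shape = (B, L, F)
        y = col @ self.params["W"].T + self.params["b"]
        return y.reshape(B, L, -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        B, L, F = self._shape
        k = self.k
        p = (k - 1) // 2
        dym = dy.reshape(B * L, -1)
        self.grads["W"] = dym.T @ self._col
        self.grads["b"] = dym.sum(axis=0)
        dcol = (dym @ self.params["W"]).reshape(B, L, F, k)
        dxp = np.zeros((B, L + k - 1, F))
        for kk in range(k):
            dxp[:, kk : kk + L, :] += dcol[:, :, :, kk]
        return dxp[:, p : p + L, :]


class Dense(Layer):
    """Position-wise fully connected layer."""

    def __init__(self, f_in: int, f_out: int, rng: np.random.Generator):
        super().__init__()
        scale = np.sqrt(2.0 / f_in)
        self.params = {
            "W": rng.normal(0.0, scale, size=(f_in, f_out)),
            "b": np.zeros(f_out),
        }

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._x
        B, L, F = x.shape
        xm = x.reshape(B * L, F)
        dym = dy.reshape(B * L, -1)
        self.grads["W"] = xm.T @ dym
        self.grads["b"] = dym.sum(axis=0)
        return (dym @ self.params["W"].T).reshape(x.shape)


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._pos = x > 0
        return np.where(self._pos, x, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._pos


class Dropout(Layer):
    """Inverted dropout; identity in eval mode."""

    def __init__(self, rate: float):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate

    def forward(self, x: np.ndarray) -> np.ndarray:
        if not self.train or self.rate == 0.0:
            self._dmask = None
            return x
        keep = 1.0 - self.rate
        self._dmask = (self.rng.random(x.shape) < keep) / keep
        return x * self._dmask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._dmask is None:
            return dy
        return dy * self._dmask


class MaskMul(Layer):
    """Zero out padding positions so '-' content never propagates."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x * self.mask[..., None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self.mask[..., None]


class BatchNorm(Layer):
    """Feature-wise batch normalization with masked statistics.

    Mean and variance are taken over unmasked (batch, position)
    elements only, so padding neither shifts the statistics nor leaks
    gradient.  Running estimates are used in eval mode.
    """

    def __init__(self, f: int, momentum: float = 0.9, eps: float = 1e-5):
        super().__init__()
        self.params = {"gamma": np.ones(f), "beta": np.zeros(f)}
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(f)
        self.running_var = np.ones(f)

    def forward(self, x: np.ndarray) -> np.ndarray:
        m = self.mask[..., None].astype(float)
        if self.train:
            cnt = max(m.sum(), 1.0)  # fully masked batches contribute nothing
            mu = (x * m).sum(axis=(0, 1)) / cnt
            var = (((x - mu) ** 2) * m).sum(axis=(0, 1)) / cnt
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mu
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
            self._cnt = cnt
        else:
            mu, var = self.running_mean, self.running_var
        self._inv_std = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mu) * self._inv_std
        self._m = m
        return self.params["gamma"] * self._xhat + self.params["beta"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        m = self._m
        xhat = self._xhat
        self.grads["gamma"] = (dy * xhat * m).sum(axis=(0, 1))
        self.grads["beta"] = (dy * m).sum(axis=(0, 1))
        dxhat = dy * self.params["gamma"]
        if not self.train:
            return dxhat * self._inv_std * m
        cnt = self._cnt
        s1 = (dxhat * m).sum(axis=(0, 1))
        s2 = (dxhat * xhat * m).sum(axis=(0, 1))
        return self._inv_std * m * (dxhat - s1 / cnt - xhat * s2 / cnt)


class BiLSTM(Layer):
    """Single bidirectional LSTM layer; outputs 2*units features.

    Gate order i, f, g, o; forget-gate bias initialized to 1.  Padding
    positions arrive zeroed, so the recurrence carries no padding
    content (the state update at a zero input still runs, but its value
    is independent of what the padding symbol was).
    """

    def __init__(self, f_in: int, units: int, rng: np.random.Generator):
        super().__init__()
        self.units = units
        self.params = {}
        for d in ("fw", "bw"):
            sx = np.sqrt(1.0 / f_in)
            sh = np.sqrt(1.0 / units)
            self.params[f"Wx_{d}"] = rng.uniform(-sx, sx, size=(f_in, 4 * units))
            self.params[f"Wh_{d}"] = rng.uniform(-sh, sh, size=(units, 4 * units))
            b = np.zeros(4 * units)
            b[units : 2 * units] = 1.0  # forget bias
            self.params[f"b_{d}"] = b

    def _run(self, x: np.ndarray, d: str) -> np.ndarray:
        B, L, _ = x.shape
        U = self.units
        Wx, Wh, b = self.params[f"Wx_{d}"], self.params[f"Wh_{d}"], self.params[f"b_{d}"]
        pre = x @ Wx + b
        ts = range(L) if d == "fw" else range(L - 1, -1, -1)
        h = np.zeros((B, U))
        c = np.zeros((B, U))
        cache = {
            k: np.empty((B, L, U))
            for k in ("i", "f", "g", "o", "c", "hc", "h_prev", "c_prev")
        }
        hs = np.empty((B, L, U))
        for t in ts:
            z = pre[:, t] + h @ Wh
            i = _sigmoid(z[:, :U])
            f = _sigmoid(z[:, U : 2 * U])
            g = np.tanh(z[:, 2 * U : 3 * U])
            o = _sigmoid(z[:, 3 * U :])
            cache["h_prev"][:, t] = h
            cache["c_prev"][:, t] = c
            c = f * c + i * g
            hc = np.tanh(c)
            h = o * hc
            for key, val in (("i", i), ("f", f), ("g", g), ("o", o), ("c", c), ("hc", hc)):
                cache[key][:, t] = val
            hs[:, t] = h
        setattr(self, f"_cache_{d}", cache)
        return hs

    def _run_back(self, x: np.ndarray, dhs: np.ndarray, d: str) -> np.ndarray:
        B, L, _ = x.shape
        U = self.units
        Wx, Wh = self.params[f"Wx_{d}"], self.params[f"Wh_{d}"]
        cache = getattr(self, f"_cache_{d}")
        ts = range(L) if d == "fw" else range(L - 1, -1, -1)
        dpre = np.empty((B, L, 4 * U))
        dWh = np.zeros_like(Wh)
        dh_next = np.zeros((B, U))
        dc_next = np.zeros((B, U))
        for t in reversed(list(ts)):
            i = cache["i"][:, t]
            f = cache["f"][:, t]
            g = cache["g"][:, t]
            o = cache["o"][:, t]
            hc = cache["hc"][:, t]
            c_prev = cache["c_prev"][:, t]
            h_prev = cache["h_prev"][:, t]
            dh = dhs[:, t] + dh_next
            do = dh * hc
            dc = dc_next + dh * o * (1.0 - hc * hc)
            di = dc * g
            dg = dc * i
            df = dc * c_prev
            dc_next = dc * f
            dz = np.concatenate(
                [
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    dg * (1.0 - g * g),
                    do * o * (1.0 - o),
                ],
                axis=1,
            )
            dpre[:, t] = dz
            dWh += h_prev.T @ dz
            dh_next = dz @ Wh.T
        xm = x.reshape(B * L, -1)
        dpm = dpre.reshape(B * L, 4 * U)
        self.grads[f"Wx_{d}"] = xm.T @ dpm
        self.grads[f"Wh_{d}"] = dWh
        self.grads[f"b_{d}"] = dpm.sum(axis=0)
        return dpre @ Wx.T

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        h_fw = self._run(x, "fw")
        h_bw = self._run(x, "bw")
        return np.concatenate([h_fw, h_bw], axis=2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        U = self.units
        dx = self._run_back(self._x, dy[:, :, :U], "fw")
        dx += self._run_back(self._x, dy[:, :, U:], "bw")
        return dx


class ResNetLayer(Layer):
    """Two FC layers with a shortcut joining their outputs.

    ``a = relu(W1 x + b1)``; ``out = relu(a + W2 a + b2)``.  The first
    layer also adapts the incoming width to ``n`` when they differ.
    """

    def __init__(self, f_in: int, n: int, rng: np.random.Generator):
        super().__init__()
        s1 = np.sqrt(2.0 / f_in)
        s2 = np.sqrt(2.0 / n)
        self.params = {
            "W1": rng.normal(0.0, s1, size=(f_in, n)),
            "b1": np.zeros(n),
            "W2": rng.normal(0.0, s2, size=(n, n)),
            "b2": np.zeros(n),
        }

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        a_pre = x @ self.params["W1"] + self.params["b1"]
        self._a_pos = a_pre > 0
        a = np.where(self._a_pos, a_pre, 0.0)
        self._a = a
        out_pre = a + a @ self.params["W2"] + self.params["b2"]
        self._o_pos = out_pre > 0
        return np.where(self._o_pos, out_pre, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x, a = self._x, self._a
        B, L, _ = x.shape
        dpre = dy * self._o_pos
        dpm = dpre.reshape(B * L, -1)
        am = a.reshape(B * L, -1)
        self.grads["W2"] = am.T @ dpm
        self.grads["b2"] = dpm.sum(axis=0)
        da = dpre + dpre @ self.params["W2"].T
        da_pre = da * self._a_pos
        dam = da_pre.reshape(B * L, -1)
        xm = x.reshape(B * L, -1)
        self.grads["W1"] = xm.T @ dam
        self.grads["b1"] = dam.sum(axis=0)
        return da_pre @ self.params["W1"].T


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(
    logits: np.ndarray, y: np.ndarray, mask: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """Masked per-position cross entropy.

    Returns ``(loss, dlogits, probs)``; loss is averaged over unmasked
    positions, and fully masked batches contribute zero loss.
    """
    probs = softmax(logits)
    m = mask.astype(float)
    cnt = m.sum()
    if cnt == 0:
        return 0.0, np.zeros_like(logits), probs
    B, L, K = logits.shape
    idx = (np.arange(B)[:, None], np.arange(L)[None, :], y)
    logp = np.log(np.clip(probs[idx], 1e-12, None))
    loss = -(logp * m).sum() / cnt
    onehot = np.zeros_like(probs)
    onehot[idx] = 1.0
    dlogits = (probs - onehot) * m[..., None] / cnt
    return float(loss), dlogits, probs


class Adam:
    """Adam optimizer over (layer, name) keyed parameter slots."""

    def __init__(self, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self._m: dict[tuple[int, str], np.ndarray] = {}
        self._v: dict[tuple[int, str], np.ndarray] = {}

    def step(self, layers: list[Layer]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for li, layer in enumerate(layers):
            for name, p in layer.params.items():
                g = layer.grads.get(name)
                if g is None:
                    continue
                key = (li, name)
                if key not in self._m:
                    self._m[key] = np.zeros_like(p)
                    self._v[key] = np.zeros_like(p)
                m = self._m[key]
                v = self._v[key]
                m *= self.beta1
                m += (1 - self.beta1) * g
                v *= self.beta2
                v += (1 - self.beta2) * g * g
                p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
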