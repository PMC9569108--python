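"""Minimal NumPy neural-network core.

Dense, embedding, 1D convolution and GRU layers with hand-written
backward passes, plus an Adam optimizer.  All layers share a simple
protocol: ``forward`` caches whatever the backward pass needs,
``backward`` accumulates parameter gradients into ``.grads`` and
returns the gradient with respect to the layer input.  Gradients are
verified against central finite differences in the test suite.

Shapes follow the usual sequence-model conventions:
``(batch, time, features)`` for recurrent/conv inputs, ``(batch,
features)`` for dense inputs.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Dense",
    "Embedding",
    "GRU",
    "Conv1D",
    "Adam",
    "relu",
    "softmax_cross_entropy",
]


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Layer:
    """Base: parameter dict + gradient dict with matching keys."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def zero_grad(self) -> None:
        for k, v in self.params.items():
            self.grads[k] = np.zeros_like(v)


class Dense(Layer):
    """Affine map with optional activation ('relu', 'tanh' or None)."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 activation: str | None = None) -> None:
        super().__init__()
        self.activation = activation
        self.params["W"] = _glorot(rng, n_in, n_out, (n_in, n_out))
        self.params["b"] = np.zeros(n_out)
        self.zero_grad()

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        z = x @ self.params["W"] + self.params["b"]
        if self.activation == "relu":
            self._z = z
            return relu(z)
        if self.activation == "tanh":
            self._out = np.tanh(z)
            return self._out
        return z

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self.activation == "relu":
            dout = dout * (self._z > 0)
        elif self.activation == "tanh":
            dout = dout * (1.0 - self._out ** 2)
        x = self._x
        # collapse any leading dims so the same layer serves 2-D and 3-D inputs
        x2 = x.reshape(-1, x.shape[-1])
        d2 = dout.reshape(-1, dout.shape[-1])
        self.grads["W"] += x2.T @ d2
        self.grads["b"] += d2.sum(axis=0)
        return dout @ self.params["W"].T


class Embedding(Layer):
    """Token-index lookup table."""

    def __init__(self, n_tokens: int, dim: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.params["E"] = rng.normal(0.0, 0.1, size=(n_tokens, dim))
        self.zero_grad()

    def forward(self, idx: np.ndarray) -> np.ndarray:
        self._idx = idx
        return self.params["E"][idx]

    def backward(self, dout: np.ndarray) -> None:
        np.add.at(self.grads["E"], self._idx, dout)


class GRU(Layer):
    """Gated recurrent unit over (batch, time, n_in) sequences.

    Gate equations (reset gate applied to the candidate's hidden
    contribution):

        z_t = sigmoid(x_t Wz + h_{t-1} Uz + bz)
        r_t = sigmoid(x_t Wr + h_{t-1} Ur + br)
        n_t = tanh(x_t Wn + r_t * (h_{t-1} Un + bn))
        h_t = (1 - z_t) * n_t + z_t * h_{t-1}
    """

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.n_hidden = n_hidden
        for g in ("z", "r", "n"):
            self.params[f"W{g}"] = _glorot(rng, n_in, n_hidden, (n_in, n_hidden))
            self.params[f"U{g}"] = _glorot(rng, n_hidden, n_hidden, (n_hidden, n_hidden))
            self.params[f"b{g}"] = np.zeros(n_hidden)
        self.zero_grad()

    def forward(self, x: np.ndarray, h0: np.ndarray | None = None) -> np.ndarray:
        B, T, _ = x.shape
        H = self.n_hidden
        p = self.params
        h = np.zeros((B, H)) if h0 is None else h0
        self._x, self._h0 = x, h
        self._cache = []
        hs = np.empty((B, T, H))
        for t in range(T):
            xt = x[:, t, :]
            z = _sigmoid(xt @ p["Wz"] + h @ p["Uz"] + p["bz"])
            r = _sigmoid(xt @ p["Wr"] + h @ p["Ur"] + p["br"])
            hu = h @ p["Un"] + p["bn"]
            n = np.tanh(xt @ p["Wn"] + r * hu)
            h_new = (1.0 - z) * n + z * h
            self._cache.append((h, z, r, n, hu))
            h = h_new
            hs[:, t, :] = h
        return hs

    def backward(self, dhs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """dhs: gradient wrt every hidden state, (B, T, H).

        Returns (dx, dh0).
        """
        p, g = self.params, self.grads
        x = self._x
        B, T, _ = x.shape
        dx = np.zeros_like(x)
        dh = np.zeros((B, self.n_hidden))
        for t in range(T - 1, -1, -1):
            dh = dh + dhs[:, t, :]
            h_prev, z, r, n, hu = self._cache[t]
            xt = x[:, t, :]
            dn = dh * (1.0 - z)
            dz = dh * (h_prev - n)
            dh_prev = dh * z
            # candidate
            da_n = dn * (1.0 - n ** 2)
            g["Wn"] += xt.T @ da_n
            dr = da_n * hu
            dhu = da_n * r
            g["Un"] += h_prev.T @ dhu
            g["bn"] += dhu.sum(axis=0)
            dh_prev += dhu @ p["Un"].T
            dxt = da_n @ p["Wn"].T
            # reset gate
            da_r = dr * r * (1.0 - r)
            g["Wr"] += xt.T @ da_r
            g["Ur"] += h_prev.T @ da_r
            g["br"] += da_r.sum(axis=0)
            dh_prev += da_r @ p["Ur"].T
            dxt += da_r @ p["Wr"].T
            # update gate
            da_z = dz * z * (1.0 - z)
            g["Wz"] += xt.T @ da_z
            g["Uz"] += h_prev.T @ da_z
            g["bz"] += da_z.sum(axis=0)
            dh_prev += da_z @ p["Uz"].T
            dxt += da_z @ p["Wz"].T
            dx[:, t, :] = dxt
            dh = dh_prev
        return dx, dh


class Conv1D(Layer):
    """'Same'-padded 1-D convolution over (batch, time, channels)."""

    def __init__(self, n_in: int, n_out: int, kernel: int,
                 rng: np.random.Generator, activation: str | None = None) -> None:
        super().__init__()
        if kernel % 2 == 0:
            raise ValueError("kernel size must be odd for same padding")
        self.kernel = kernel
        self.activation = activation
        self.params["W"] = _glorot(rng, n_in * kernel, n_out, (kernel, n_in, n_out))
        self.params["b"] = np.zeros(n_out)
        self.zero_grad()

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        B, T, C = x.shape
        k = self.kernel
        pad = k // 2
        xp = np.pad(x, ((0, 0), (pad, pad), (0, 0)))
        cols = np.empty((B, T, k, C))
        for i in range(k):
            cols[:, :, i, :] = xp[:, i:i + T, :]
        return cols

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        cols = self._im2col(x)          # (B, T, k, C)
        self._cols = cols
        W = self.params["W"]            # (k, C, O)
        z = np.einsum("btkc,kco->bto", cols, W) + self.params["b"]
        if self.activation == "relu":
            self._z = z
            return relu(z)
        return z

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self.activation == "relu":
            dout = dout * (self._z > 0)
        W = self.params["W"]
        self.grads["W"] += np.einsum("btkc,bto->kco", self._cols, dout)
        self.grads["b"] += dout.sum(axis=(0, 1))
        dcols = np.einsum("bto,kco->btkc", dout, W)
        B, T, C = self._shape
        k = self.kernel
        pad = k // 2
        dxp = np.zeros((B, T + 2 * pad, C))
        for i in range(k):
            dxp[:, i:i + T, :] += dcols[:, :, i, :]
        return dxp[:, pad:pad + T, :]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softmax_cross_entropy(logits: np.ndarray, targets: np.ndarray,
                          sample_weight: np.ndarray | None = None
                          ) -> tuple[float, np.ndarray]:
    """Mean cross-entropy and its gradient wrt logits.

    ``logits``: (N, V); ``targets``: (N,) int; ``sample_weight``: (N,)
    non-negative, entries may be zero to mask positions out.  The loss
    is sum(w_i * ce_i) / sum(i: w_i participates) where the normalizer
    is the count of unmasked positions (weights scale, masks exclude).
    """
    N, _ = logits.shape
    if sample_weight is None:
        sample_weight = np.ones(N)
    m = logits.max(axis=1, keepdims=True)
    ex = np.exp(logits - m)
    probs = ex / ex.sum(axis=1, keepdims=True)
    logp = (logits - m) - np.log(ex.sum(axis=1, keepdims=True))
    nll = -logp[np.arange(N), targets]
    denom = float(np.count_nonzero(sample_weight))
    if denom == 0:
        return 0.0, np.zeros_like(logits)
    loss = float((sample_weight * nll).sum() / denom)
    dlogits = probs.copy()
    dlogits[np.arange(N), targets] -= 1.0
    dlogits *= (sample_weight / denom)[:, None]
    return loss, dlogits


class Adam:
    """Adam over a list of layers (their params/grads dicts)."""

    def __init__(self, layers, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.layers = list(layers)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [{k: np.zeros_like(v) for k, v in ly.params.items()} for ly in self.layers]
        self.v = [{k: np.zeros_like(v) for k, v in ly.params.items()} for ly in self.layers]

    def zero_grad(self) -> None:
        for ly in self.layers:
            ly.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for ly, m, v in zip(self.layers, self.m, self.v):
            for k, p in ly.params.items():
                g = ly.grads[k]
                m[k] = self.b1 * m[k] + (1 - self.b1) * g
                v[k] = self.b2 * v[k] + (1 - self.b2) * g * g
                p -= self.lr * (m[k] / b1t) / (np.sqrt(v[k] / b2t) + self.eps)
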