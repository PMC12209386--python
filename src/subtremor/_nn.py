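"""Minimal feed-forward/recurrent layers with hand-written backpropagation.

Everything operates on numpy arrays; parameters and gradients live in flat
dicts keyed by layer-local names so one Adam instance can update a whole
model.  Shapes: sequence inputs are (batch, time, features); 1-D
convolutional inputs are (batch, channels, length).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "sigmoid",
    "glorot",
    "Dense",
    "LSTMLayer",
    "Conv1D",
    "MaxPool1D",
    "FeatureNormalizer",
    "Adam",
    "softmax",
    "cross_entropy_with_grad",
]


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def glorot(rng: np.random.Generator, n_in: int, n_out: int,
           shape: tuple[int, ...] | None = None) -> np.ndarray:
    limit = np.sqrt(6.0 / (n_in + n_out))
    return rng.uniform(-limit, limit, size=shape or (n_in, n_out))


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy_with_grad(logits: np.ndarray,
                            labels: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """Mean categorical cross-entropy; returns (loss, probs, dlogits)."""
    probs = softmax(logits)
    n = logits.shape[0]
    eps = 1e-12
    loss = -float(np.mean(np.log(probs[np.arange(n), labels] + eps)))
    dlogits = probs.copy()
    dlogits[np.arange(n), labels] -= 1.0
    return loss, probs, dlogits / n


class Dense:
    """Affine layer y = x W + b with optional ReLU."""

    def __init__(self, rng: np.random.Generator, n_in: int, n_out: int,
                 relu: bool = False):
        self.relu = relu
        self.params = {"W": glorot(rng, n_in, n_out), "b": np.zeros(n_out)}
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x: np.ndarray) -> np.ndarray:
        z = x @ self.params["W"] + self.params["b"]
        self._cache = (x, z)
        return np.maximum(z, 0.0) if self.relu else z

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x, z = self._cache
        if self.relu:
            dout = dout * (z > 0)
        self.grads["W"] += x.T @ dout
        self.grads["b"] += dout.sum(axis=0)
        return dout @ self.params["W"].T


class LSTMLayer:
    """Single LSTM layer unrolled over time.

    Gate order in the fused weight matrices is (input, forget, output,
    candidate).  Per step: I, f, O are logistic sigmoids of the affine
    forms x U + h_prev W (+ b); the candidate is tanh of its affine form;
    C_t = f * C_{t-1} + I * Cbar_t and h_t = O * tanh(C_t).
    """

    def __init__(self, rng: np.random.Generator, n_in: int, n_hidden: int,
                 bias: bool = True):
        self.n_hidden = n_hidden
        self.params = {
            "U": glorot(rng, n_in, 4 * n_hidden),
            "W": glorot(rng, n_hidden, 4 * n_hidden),
            "b": np.zeros(4 * n_hidden),
        }
        if bias:
            # forget-gate bias at 1: standard trick for gradient flow
            self.params["b"][n_hidden:2 * n_hidden] = 1.0
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x: np.ndarray) -> np.ndarray:
        """x: (B, T, D) -> hidden sequence (B, T, H)."""
        B, T, _ = x.shape
        H = self.n_hidden
        h = np.zeros((B, H))
        C = np.zeros((B, H))
        hs = np.empty((B, T, H))
        self._cache = []
        for t in range(T):
            xt = x[:, t, :]
            z = xt @ self.params["U"] + h @ self.params["W"] + self.params["b"]
            i = sigmoid(z[:, :H])
            f = sigmoid(z[:, H:2 * H])
            o = sigmoid(z[:, 2 * H:3 * H])
            cbar = np.tanh(z[:, 3 * H:])
            C_prev = C
            C = f * C_prev + i * cbar
            tc = np.tanh(C)
            h_prev = h
            h = o * tc
            hs[:, t, :] = h
            self._cache.append((xt, h_prev, C_prev, i, f, o, cbar, C, tc))
        self._x_shape = x.shape
        return hs

    def backward(self, dhs: np.ndarray) -> np.ndarray:
        """dhs: gradient w.r.t. the hidden sequence; returns dx."""
        B, T, _ = self._x_shape
        H = self.n_hidden
        dx = np.zeros(self._x_shape)
        dh_next = np.zeros((B, H))
        dC_next = np.zeros((B, H))
        for t in reversed(range(T)):
            xt, h_prev, C_prev, i, f, o, cbar, C, tc = self._cache[t]
            dh = dhs[:, t, :] + dh_next
            do = dh * tc
            dC = dC_next + dh * o * (1.0 - tc**2)
            di = dC * cbar
            dcbar = dC * i
            df = dC * C_prev
            dC_next = dC * f
            dz = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f), do * o * (1 - o),
                 dcbar * (1 - cbar**2)], axis=1)
            self.grads["U"] += xt.T @ dz
            self.grads["W"] += h_prev.T @ dz
            self.grads["b"] += dz.sum(axis=0)
            dh_next = dz @ self.params["W"].T
            dx[:, t, :] = dz @ self.params["U"].T
        return dx


class Conv1D:
    """Valid 1-D convolution (cross-correlation) with ReLU activation.

    x: (B, C, L) -> (B, F, L - K + 1).
    """

    def __init__(self, rng: np.random.Generator, n_in: int, n_filters: int,
                 kernel: int):
        self.kernel = kernel
        fan_in, fan_out = n_in * kernel, n_filters * kernel
        self.params = {
            "W": glorot(rng, fan_in, fan_out, shape=(n_filters, n_in, kernel)),
            "b": np.zeros(n_filters),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x: np.ndarray) -> np.ndarray:
        windows = np.lib.stride_tricks.sliding_window_view(x, self.kernel, axis=2)
        z = np.einsum("bclk,fck->bfl", windows, self.params["W"]) \
            + self.params["b"][None, :, None]
        self._cache = (windows, x.shape, z)
        return np.maximum(z, 0.0)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        windows, x_shape, z = self._cache
        dout = dout * (z > 0)
        self.grads["W"] += np.einsum("bclk,bfl->fck", windows, dout)
        self.grads["b"] += dout.sum(axis=(0, 2))
        dx = np.zeros(x_shape)
        L_out = dout.shape[2]
        for k in range(self.kernel):
            dx[:, :, k:k + L_out] += np.einsum(
                "bfl,fc->bcl", dout, self.params["W"][:, :, k])
        return dx


class MaxPool1D:
    """Non-overlapping max pooling along the last axis (trailing remainder
    dropped)."""

    def __init__(self, size: int = 2):
        self.size = size
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, C, L = x.shape
        L_out = L // self.size
        xr = x[:, :, :L_out * self.size].reshape(B, C, L_out, self.size)
        self._argmax = xr.argmax(axis=3)
        self._x_shape = x.shape
        return xr.max(axis=3)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        B, C, L_out = dout.shape
        dx = np.zeros(self._x_shape)
        dxr = dx[:, :, :L_out * self.size].reshape(B, C, L_out, self.size)
        b, c, l = np.ogrid[:B, :C, :L_out]
        dxr[b, c, l, self._argmax] = dout
        return dx


class FeatureNormalizer:
    """Feature-wise input normalization with statistics frozen at fit time.

    Plays the role of a batch-normalization layer operating in inference
    mode: features are standardized with mean/std accumulated from the
    training set; no gradient flows through the statistics.
    """

    def __init__(self) -> None:
        self.mean: np.ndarray | None = None
        self.std: np.ndarray | None = None
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def fit(self, x: np.ndarray) -> "FeatureNormalizer":
        """x: (N, T, D) stacked training sequences."""
        flat = x.reshape(-1, x.shape[-1])
        self.mean = flat.mean(axis=0)
        self.std = flat.std(axis=0) + 1e-8
        return self

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.mean is None:
            raise RuntimeError("normalizer not fitted")
        return (x - self.mean) / self.std

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout / self.std


class Adam:
    """Adam over a list of layers (uses each layer's params/grads dicts)."""

    def __init__(self, layers, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8, l2: float = 0.0):
        self.layers = [l for l in layers if l.params]
        self.lr, self.beta1, self.beta2, self.eps, self.l2 = lr, beta1, beta2, eps, l2
        self.t = 0
        self.m = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers]
        self.v = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers]

    def zero_grad(self) -> None:
        for layer in self.layers:
            for g in layer.grads.values():
                g[...] = 0.0

    def step(self) -> None:
        self.t += 1
        b1c = 1.0 - self.beta1**self.t
        b2c = 1.0 - self.beta2**self.t
        for layer, m, v in zip(self.layers, self.m, self.v):
            for k, p in layer.params.items():
                g = layer.grads[k]
                if self.l2 and k != "b":
                    g = g + self.l2 * p
                m[k] = self.beta1 * m[k] + (1 - self.beta1) * g
                v[k] = self.beta2 * v[k] + (1 - self.beta2) * g**2
                p -= self.lr * (m[k] / b1c) / (np.sqrt(v[k] / b2c) + self.eps)


class SGD:
    """Plain (optionally momentum-free) stochastic gradient descent."""

    def __init__(self, layers, lr: float = 1e-2, l2: float = 0.0):
        self.layers = [l for l in layers if l.params]
        self.lr, self.l2 = lr, l2

    def zero_grad(self) -> None:
        for layer in self.layers:
            for g in layer.grads.values():
                g[...] = 0.0

    def step(self) -> None:
        for layer in self.layers:
            for k, p in layer.params.items():
                g = layer.grads[k]
                if self.l2 and k != "b":
                    g = g + self.l2 * p
                p -= self.lr * g
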