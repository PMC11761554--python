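"""Minimal fully-connected network with manual backpropagation.

The voxel-wise fitter is a small multilayer perceptron: repeated blocks of
``linear -> activation -> dropout`` followed by a linear head.  The forward
and backward passes are plain NumPy; the gradient of the physics term is
supplied externally by the caller (it flows through the closed-form
relaxation models, not through generic autodiff).
"""

from __future__ import annotations

import numpy as np

__all__ = ["ACTIVATIONS", "MLP", "make_optimizer"]


def _relu(z):
    return np.maximum(z, 0.0), (z > 0).astype(z.dtype)


def _leaky_relu(z, alpha=0.01):
    return np.where(z > 0, z, alpha * z), np.where(z > 0, 1.0, alpha)


def _tanh(z):
    a = np.tanh(z)
    return a, 1.0 - a * a


def _gelu(z):
    # tanh approximation; derivative computed consistently with it
    c = np.sqrt(2.0 / np.pi)
    u = c * (z + 0.044715 * z**3)
    t = np.tanh(u)
    a = 0.5 * z * (1.0 + t)
    du = c * (1.0 + 3 * 0.044715 * z**2)
    da = 0.5 * (1.0 + t) + 0.5 * z * (1.0 - t * t) * du
    return a, da


def _swish(z):
    s = 1.0 / (1.0 + np.exp(-z))
    a = z * s
    return a, s * (1.0 + z * (1.0 - s))


ACTIVATIONS = {
    "relu": _relu,
    "leaky_relu": _leaky_relu,
    "tanh": _tanh,
    "gelu": _gelu,
    "swish": _swish,
}


class MLP:
    """Feed-forward network: (linear-activation-dropout) blocks + linear head."""

    def __init__(self, sizes: list[int], activation: str, dropout_rate: float,
                 rng: np.random.Generator):
        if activation not in ACTIVATIONS:
            raise ValueError(f"unknown activation {activation!r}")
        if not 0.0 <= dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        self.activation = activation
        self.dropout_rate = float(dropout_rate)
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            scale = np.sqrt(2.0 / fan_in)  # He init, suits ReLU-family
            self.weights.append(rng.standard_normal((fan_in, fan_out)) * scale)
            self.biases.append(np.zeros(fan_out))

    @property
    def params(self) -> list[np.ndarray]:
        return self.weights + self.biases

    def copy_params(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params]

    def set_params(self, params: list[np.ndarray]) -> None:
        k = len(self.weights)
        self.weights = [p.copy() for p in params[:k]]
        self.biases = [p.copy() for p in params[k:]]

    def forward(self, X: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None):
        """Return the head output and a cache for :meth:`backward`."""
        act = ACTIVATIONS[self.activation]
        keep = 1.0 - self.dropout_rate
        h = X
        cache = []
        for i, (W, b) in enumerate(zip(self.weights, self.biases)):
            z = h @ W + b
            if i == len(self.weights) - 1:  # linear head
                cache.append((h, None, None))
                h = z
                break
            a, da = act(z)
            if train and self.dropout_rate > 0:
                mask = (rng.uniform(size=a.shape) < keep) / keep
                a = a * mask
                da = da * mask
            cache.append((h, da, None))
            h = a
        return h, cache

    def backward(self, cache, dout: np.ndarray):
        """Gradients of a scalar loss w.r.t. all weights, given d(loss)/d(head)."""
        gW = [None] * len(self.weights)
        gb = [None] * len(self.biases)
        delta = dout
        for i in reversed(range(len(self.weights))):
            h, da, _ = cache[i]
            gW[i] = h.T @ delta
            gb[i] = delta.sum(axis=0)
            if i > 0:
                delta = (delta @ self.weights[i].T) * cache[i - 1][1] \
                    if cache[i - 1][1] is not None else delta @ self.weights[i].T
                # note: cache[i-1][1] is the activation derivative of block i-1
        return gW + gb


class _Adam:
    def __init__(self, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = self.v = None
        self.t = 0

    def step(self, params, grads):
        if self.m is None:
            self.m = [np.zeros_like(p) for p in params]
            self.v = [np.zeros_like(p) for p in params]
        self.t += 1
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class _SGD:
    def __init__(self, lr, momentum=0.9):
        self.lr, self.mu = lr, momentum
        self.v = None

    def step(self, params, grads):
        if self.v is None:
            self.v = [np.zeros_like(p) for p in params]
        for p, g, v in zip(params, grads, self.v):
            v *= self.mu
            v += g
            p -= self.lr * v


class _RMSProp:
    def __init__(self, lr, rho=0.9, eps=1e-8):
        self.lr, self.rho, self.eps = lr, rho, eps
        self.v = None

    def step(self, params, grads):
        if self.v is None:
            self.v = [np.zeros_like(p) for p in params]
        for p, g, v in zip(params, grads, self.v):
            v *= self.rho
            v += (1 - self.rho) * g * g
            p -= self.lr * g / (np.sqrt(v) + self.eps)


def make_optimizer(name: str, lr: float):
    try:
        return {"adam": _Adam, "sgd": _SGD, "rmsprop": _RMSProp}[name](lr)
    except KeyError:
        raise ValueError(f"unknown optimizer {name!r}") from None
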