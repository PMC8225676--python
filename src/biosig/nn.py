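"""Minimal feed-forward neural-network engine (numpy).

Dense layers, SeLU + alpha-dropout, ReLU + standard dropout, multiplicative
Gaussian input noise, Tanh, row-wise L2 normalization, and an Adam
optimizer — the exact ingredients of the signaturizer architectures.  The
engine is deliberately small: forward passes cache what backward needs,
parameters are shared across Siamese branches simply by reusing the same
layer objects, and all randomness flows through an explicit
``numpy.random.Generator`` so training is deterministic given a seed.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Dense",
    "SeLU",
    "ReLU",
    "Tanh",
    "AlphaDropout",
    "Dropout",
    "GaussianDropout",
    "L2Norm",
    "Network",
    "Adam",
]

# SeLU constants (self-normalizing networks)
_SELU_ALPHA = 1.6732632423543772
_SELU_LAMBDA = 1.0507009873554805
# alpha-dropout saturation value: -lambda * alpha
_ALPHA_PRIME = -_SELU_LAMBDA * _SELU_ALPHA


class Layer:
    """Base layer; stateless layers only implement forward/backward."""

    params: list
    grads: list

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x, training, rng):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad, cache):  # pragma: no cover - interface
        raise NotImplementedError

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.params))


class Dense(Layer):
    """Affine layer ``y = x W + b``.

    ``init`` selects the weight scale: "lecun" (SeLU layers), "he" (ReLU
    layers) or "glorot" (Tanh output head).
    """

    def __init__(self, d_in: int, d_out: int, rng, init: str = "lecun") -> None:
        super().__init__()
        if init == "lecun":
            scale = 1.0 / np.sqrt(d_in)
        elif init == "he":
            scale = np.sqrt(2.0 / d_in)
        elif init == "glorot":
            scale = np.sqrt(2.0 / (d_in + d_out))
        else:
            raise ValueError(f"unknown init {init!r}")
        self.W = rng.standard_normal((d_in, d_out)) * scale
        self.b = np.zeros(d_out)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, training, rng):
        return x @ self.W + self.b, x

    def backward(self, grad, cache):
        x = cache
        self.grads[0] += x.T @ grad
        self.grads[1] += grad.sum(axis=0)
        return grad @ self.W.T


class SeLU(Layer):
    def forward(self, x, training, rng):
        y = _SELU_LAMBDA * np.where(x > 0, x, _SELU_ALPHA * np.expm1(x))
        return y, x

    def backward(self, grad, cache):
        x = cache
        dydx = _SELU_LAMBDA * np.where(x > 0, 1.0, _SELU_ALPHA * np.exp(x))
        return grad * dydx


class ReLU(Layer):
    def forward(self, x, training, rng):
        return np.maximum(x, 0.0), x

    def backward(self, grad, cache):
        return grad * (cache > 0)


class Tanh(Layer):
    def forward(self, x, training, rng):
        y = np.tanh(x)
        return y, y

    def backward(self, grad, cache):
        return grad * (1.0 - cache**2)


class GaussianDropout(Layer):
    """Multiplicative Gaussian noise ``x * N(1, sigma^2)``; identity at inference."""

    def __init__(self, sigma: float) -> None:
        super().__init__()
        self.sigma = float(sigma)

    def forward(self, x, training, rng):
        if not training or self.sigma == 0:
            return x, None
        noise = rng.normal(1.0, self.sigma, size=x.shape)
        return x * noise, noise

    def backward(self, grad, cache):
        return grad if cache is None else grad * cache


class Dropout(Layer):
    """Standard inverted dropout; identity at inference."""

    def __init__(self, rate: float) -> None:
        super().__init__()
        self.rate = float(rate)

    def forward(self, x, training, rng):
        if not training or self.rate == 0:
            return x, None
        keep = 1.0 - self.rate
        mask = (rng.random(x.shape) < keep) / keep
        return x * mask, mask

    def backward(self, grad, cache):
        return grad if cache is None else grad * cache


class AlphaDropout(Layer):
    """Alpha-dropout: drops units to the SeLU saturation value and applies
    the affine correction that preserves zero mean / unit variance."""

    def __init__(self, rate: float) -> None:
        super().__init__()
        self.rate = float(rate)
        q = 1.0 - self.rate
        # variance-preserving affine correction for standardized inputs
        self.a = (q + _ALPHA_PRIME**2 * q * (1 - q)) ** -0.5 if self.rate else 1.0
        self.b = -self.a * (1 - q) * _ALPHA_PRIME

    def forward(self, x, training, rng):
        if not training or self.rate == 0:
            return x, None
        mask = rng.random(x.shape) >= self.rate
        y = self.a * np.where(mask, x, _ALPHA_PRIME) + self.b
        return y, mask

    def backward(self, grad, cache):
        if cache is None:
            return grad
        return grad * (self.a * cache)


class L2Norm(Layer):
    """Row-wise L2 normalization with a degenerate-row guard.

    A row whose norm is numerically zero (possible only for pathological
    inputs) is replaced by the fixed unit vector e_1 so the unit-norm
    output contract holds for every input.
    """

    EPS = 1e-12

    def forward(self, x, training, rng):
        norms = np.linalg.norm(x, axis=-1, keepdims=True)
        degenerate = norms[..., 0] < self.EPS
        safe = np.maximum(norms, self.EPS)
        y = x / safe
        if np.any(degenerate):
            y = y.copy()
            y[degenerate] = 0.0
            y[degenerate, 0] = 1.0
        return y, (x, safe, degenerate)

    def backward(self, grad, cache):
        x, norms, degenerate = cache
        dot = np.sum(x * grad, axis=-1, keepdims=True)
        gx = grad / norms - x * dot / norms**3
        if np.any(degenerate):
            gx[degenerate] = 0.0
        return gx


class Network:
    """A sequential stack of layers with shared-parameter forward/backward."""

    def __init__(self, layers: list) -> None:
        self.layers = layers

    def forward(self, x, training: bool = False, rng=None):
        """Return (output, caches); caches feed :meth:`backward`."""
        caches = []
        for layer in self.layers:
            x, cache = layer.forward(x, training, rng)
            caches.append(cache)
        return x, caches

    def predict(self, x):
        return self.forward(np.asarray(x, dtype=float), training=False)[0]

    def backward(self, grad, caches):
        """Backpropagate, accumulating parameter gradients in each layer."""
        for layer, cache in zip(reversed(self.layers), reversed(caches)):
            grad = layer.backward(grad, cache)
        return grad

    def zero_grad(self) -> None:
        for layer in self.layers:
            for g in layer.grads:
                g[...] = 0.0

    def parameters(self):
        return [p for layer in self.layers for p in layer.params]

    def gradients(self):
        return [g for layer in self.layers for g in layer.grads]

    def n_parameters(self) -> int:
        return int(sum(layer.n_parameters() for layer in self.layers))

    def get_weights(self):
        return [p.copy() for p in self.parameters()]

    def set_weights(self, weights) -> None:
        for p, w in zip(self.parameters(), weights):
            p[...] = w


class Adam:
    """Adam optimizer with the standard bias-corrected moment estimates."""

    def __init__(
        self,
        network: Network,
        learning_rate: float = 1e-4,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> None:
        self.net = network
        self.lr = learning_rate
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p) for p in network.parameters()]
        self.v = [np.zeros_like(p) for p in network.parameters()]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(
            self.net.parameters(), self.net.gradients(), self.m, self.v
        ):
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g**2
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
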