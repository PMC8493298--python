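"""Minimal feedforward network engine (numpy, reverse-mode by hand).

Just what the reduced-order networks need: dense layers, ELU activations,
Glorot initialization from an explicit generator, an Adam optimizer, and
exact input gradients (the joint autoencoder/dynamics loss backpropagates
through the decoder into the dynamics network).  Parameters and activations
are single precision (ample for min-max-normalized targets, and about twice
as fast in BLAS); everything is deterministic given the seed.
"""

from __future__ import annotations

import numpy as np

__all__ = ["MLP", "Adam", "FourierLift"]


def _elu(x):
    return np.where(x > 0, x, np.expm1(np.minimum(x, 0.0)))


def _elu_grad(x):
    return np.where(x > 0, 1.0, np.exp(np.minimum(x, 0.0)))


class MLP:
    """Fully connected network with ELU hidden activations, linear output.

    ``sizes = (n_in, h1, ..., n_out)``.  ``forward`` caches activations for
    a subsequent ``backward``, which fills ``grads`` and returns the
    gradient with respect to the input batch.
    """

    def __init__(self, sizes, rng: np.random.Generator, dtype=np.float32):
        self.sizes = tuple(int(s) for s in sizes)
        self.dtype = np.dtype(dtype)
        self.weights = []
        self.biases = []
        for fan_in, fan_out in zip(self.sizes[:-1], self.sizes[1:]):
            bound = np.sqrt(6.0 / (fan_in + fan_out))
            w = rng.uniform(-bound, bound, size=(fan_in, fan_out))
            self.weights.append(w.astype(self.dtype))
            self.biases.append(np.zeros(fan_out, dtype=self.dtype))
        self.grads_w = [np.zeros_like(w) for w in self.weights]
        self.grads_b = [np.zeros_like(b) for b in self.biases]
        self._cache = None

    # -- parameter plumbing -------------------------------------------------
    @property
    def params(self):
        return self.weights + self.biases

    @property
    def grads(self):
        return self.grads_w + self.grads_b

    def state(self):
        return [p.copy() for p in self.params]

    def load_state(self, state):
        for p, s in zip(self.params, state):
            p[...] = s

    # -- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=self.dtype))
        pre_acts = []
        acts = [x]
        h = x
        n_layers = len(self.weights)
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            z = h @ w + b
            pre_acts.append(z)
            h = z if i == n_layers - 1 else _elu(z)
            acts.append(h)
        self._cache = (pre_acts, acts)
        return h

    def __call__(self, x):
        return self.forward(x)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        """Backpropagate d(loss)/d(output); returns d(loss)/d(input)."""
        if self._cache is None:
            raise RuntimeError("backward called before forward")
        pre_acts, acts = self._cache
        g = np.atleast_2d(np.asarray(grad_out, dtype=self.dtype))
        n_layers = len(self.weights)
        for i in range(n_layers - 1, -1, -1):
            if i != n_layers - 1:
                g = g * _elu_grad(pre_acts[i])
            self.grads_w[i] = acts[i].T @ g
            self.grads_b[i] = g.sum(axis=0)
            g = g @ self.weights[i].T
        return g


class FourierLift:
    """Parameter-free sinusoidal feature map ``z -> [z, sin(2 pi k z),
    cos(2 pi k z)]`` for ``k = 1..K``, applied componentwise.

    Used at the decoder input: reduced-order coordinates of travelling
    fronts oscillate along the latent phase direction, and a plain dense
    stack is biased against such high-frequency maps.  Gradients flow
    through the features to the input (the reduced-dynamics network trains
    through the lift).  ``K = 0`` is the identity.
    """

    def __init__(self, n_in: int, n_modes: int):
        self.n_in = int(n_in)
        self.n_modes = int(n_modes)
        self._z = None

    @property
    def out_dim(self) -> int:
        return self.n_in * (1 + 2 * self.n_modes)

    def forward(self, z: np.ndarray) -> np.ndarray:
        z = np.atleast_2d(z)
        self._z = z
        if self.n_modes == 0:
            return z
        cols = [z]
        for k in range(1, self.n_modes + 1):
            cols.append(np.sin(2 * np.pi * k * z))
            cols.append(np.cos(2 * np.pi * k * z))
        return np.concatenate(cols, axis=1)

    def __call__(self, z):
        return self.forward(z)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        if self.n_modes == 0:
            return grad_out
        z, n = self._z, self.n_in
        g = grad_out[:, :n].copy()
        for k in range(1, self.n_modes + 1):
            gs = grad_out[:, n * (2 * k - 1): n * 2 * k]
            gc = grad_out[:, n * 2 * k: n * (2 * k + 1)]
            w = 2 * np.pi * k
            g += gs * w * np.cos(w * z) - gc * w * np.sin(w * z)
        return g


class Adam:
    """Adam over a flat list of parameter arrays (updated in place)."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in self.params]
        self.v = [np.zeros_like(p) for p in self.params]
        self.t = 0

    def step(self, grads):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        corr1 = 1.0 - b1 ** self.t
        corr2 = 1.0 - b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            p -= self.lr * (m / corr1) / (np.sqrt(v / corr2) + self.eps)
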