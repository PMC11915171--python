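"""Minimal numpy neural-net machinery: MLP with manual backprop + Adam.

Shared by the attention classifier (``sann``) and the neural Cox model
(``baselines``). Kept deliberately small: dense ReLU layers, inverted
dropout, Adam with fixed betas. All randomness flows through explicit
``numpy.random.Generator`` instances for seeded reproducibility.
"""

from __future__ import annotations

import numpy as np

__all__ = ["MLP", "Adam", "sigmoid"]


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class MLP:
    """Fully connected ReLU network with a linear output layer.

    ``sizes = [d_in, h1, ..., out]``; with no hidden layers this is a
    plain linear map (used for the linear neural-Cox variant).
    """

    def __init__(self, sizes: list[int], rng: np.random.Generator):
        self.sizes = list(sizes)
        self.W: list[np.ndarray] = []
        self.b: list[np.ndarray] = []
        for d_in, d_out in zip(sizes[:-1], sizes[1:]):
            scale = np.sqrt(2.0 / d_in)  # He init for ReLU hiddens
            self.W.append(rng.normal(0.0, scale, size=(d_in, d_out)))
            self.b.append(np.zeros(d_out))

    # -- parameter plumbing -------------------------------------------------
    def parameters(self) -> list[np.ndarray]:
        out = []
        for W, b in zip(self.W, self.b):
            out.extend([W, b])
        return out

    def set_parameters(self, params: list[np.ndarray]) -> None:
        for i in range(len(self.W)):
            self.W[i] = params[2 * i]
            self.b[i] = params[2 * i + 1]

    # -- forward / backward -------------------------------------------------
    def forward(
        self,
        X: np.ndarray,
        dropout: float = 0.0,
        rng: np.random.Generator | None = None,
    ):
        """Returns (output, cache). Dropout (inverted) is applied to hidden
        activations only when ``dropout > 0`` and an rng is supplied."""
        h = X
        caches = []
        n_layers = len(self.W)
        for i, (W, b) in enumerate(zip(self.W, self.b)):
            z = h @ W + b
            last = i == n_layers - 1
            if last:
                caches.append((h, z, None, None))
                h = z
            else:
                a = np.maximum(z, 0.0)
                mask = None
                if dropout > 0.0 and rng is not None:
                    mask = (rng.uniform(size=a.shape) >= dropout) / (1.0 - dropout)
                    a = a * mask
                caches.append((h, z, a, mask))
                h = a
        return h, caches

    def backward(self, caches, dout: np.ndarray):
        """Returns (dX, grads) with grads aligned to :meth:`parameters`."""
        grads_W = [None] * len(self.W)
        grads_b = [None] * len(self.b)
        d = dout
        for i in reversed(range(len(self.W))):
            h_in, z, a, mask = caches[i]
            if i != len(self.W) - 1:
                if mask is not None:
                    d = d * mask
                d = d * (z > 0.0)
            grads_W[i] = h_in.T @ d
            grads_b[i] = d.sum(axis=0)
            d = d @ self.W[i].T
        grads = []
        for gW, gb in zip(grads_W, grads_b):
            grads.extend([gW, gb])
        return d, grads


class Adam:
    """Adam with fixed betas (0.9, 0.999) and eps 1e-8."""

    def __init__(self, params: list[np.ndarray], lr: float):
        self.lr = lr
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for i, (p, g) in enumerate(zip(params, grads)):
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + eps)
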