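"""Minimal feedforward networks with explicit reverse-mode gradients.

The rollout differentiates through up to ~100 Euler steps, each containing
one flux-network evaluation, so the backward pass is written as explicit
vector-Jacobian products: ``forward`` returns a cache, ``backward`` consumes
it, accumulates parameter gradients, and returns the input gradient.  All
arrays are float64 and batched along the first axis.
"""

from __future__ import annotations

import numpy as np

__all__ = ["MLP", "Adam", "softplus", "softplus_inv", "sigmoid"]


def softplus(x):
    # numerically stable log(1 + e^x)
    return np.logaddexp(0.0, x)


def softplus_inv(y):
    """Inverse of softplus for y > 0 (used to seed output biases)."""
    y = np.asarray(y, dtype=float)
    return y + np.log(-np.expm1(-y))


def sigmoid(x):
    return 0.5 * (1.0 + np.tanh(0.5 * x))


_ACTS = {
    "tanh": (np.tanh, lambda a: 1.0 - a * a),          # derivative from activation value
    "relu": (lambda x: np.maximum(x, 0.0), lambda a: (a > 0).astype(float)),
}


class MLP:
    """Fully connected net, tanh hidden layers, linear output.

    ``sizes`` lists layer widths input->output.  ``out_scale`` shrinks the
    initial output-layer weights; the rollout starts near the identity
    (fluxes ~ 0) when this is small, which is the residual-network regime
    the training relies on.
    """

    def __init__(self, sizes, activation="tanh", rng=None, out_scale=1.0):
        if activation not in _ACTS:
            raise ValueError(f"unknown activation {activation!r}")
        rng = rng or np.random.default_rng(0)
        self.sizes = list(sizes)
        self.activation = activation
        self.W, self.b = [], []
        for li, (n_in, n_out) in enumerate(zip(sizes[:-1], sizes[1:])):
            scale = np.sqrt(2.0 / (n_in + n_out))
            if li == len(sizes) - 2:
                scale *= out_scale
            self.W.append(rng.normal(0.0, scale, size=(n_in, n_out)))
            self.b.append(np.zeros(n_out))
        self.zero_grad()

    # -- parameter bookkeeping ------------------------------------------
    def zero_grad(self):
        self.gW = [np.zeros_like(w) for w in self.W]
        self.gb = [np.zeros_like(b) for b in self.b]

    def parameters(self):
        return self.W + self.b

    def gradients(self):
        return self.gW + self.gb

    def get_flat(self) -> np.ndarray:
        return np.concatenate([p.ravel() for p in self.parameters()])

    def set_flat(self, theta: np.ndarray) -> None:
        pos = 0
        for p in self.parameters():
            p[...] = theta[pos:pos + p.size].reshape(p.shape)
            pos += p.size

    def copy_params(self):
        return [p.copy() for p in self.parameters()]

    def restore_params(self, saved):
        for p, s in zip(self.parameters(), saved):
            p[...] = s

    # -- forward / backward ---------------------------------------------
    def forward(self, x: np.ndarray):
        """Return (output, cache); x is (batch, n_in)."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if x.shape[1] != self.sizes[0]:
            raise ValueError(
                f"input dimension {x.shape[1]} != expected {self.sizes[0]}"
            )
        act, _ = _ACTS[self.activation]
        cache = [x]
        h = x
        n_layers = len(self.W)
        for li, (w, b) in enumerate(zip(self.W, self.b)):
            z = h @ w + b
            h = z if li == n_layers - 1 else act(z)
            cache.append(h)
        return h, cache

    def __call__(self, x):
        return self.forward(x)[0]

    def backward(self, cache, gout: np.ndarray) -> np.ndarray:
        """Accumulate parameter grads for one cached forward; return dL/dx."""
        _, dact = _ACTS[self.activation]
        g = np.atleast_2d(gout)
        n_layers = len(self.W)
        for li in range(n_layers - 1, -1, -1):
            h_in = cache[li]
            if li != n_layers - 1:
                g = g * dact(cache[li + 1])
            self.gW[li] += h_in.T @ g
            self.gb[li] += g.sum(axis=0)
            g = g @ self.W[li].T
        return g


class Adam:
    """Adaptive-moment gradient descent over a list of parameter arrays."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in self.params]
        self.v = [np.zeros_like(p) for p in self.params]
        self.t = 0

    def step(self, grads):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        corr1 = 1.0 - b1 ** self.t
        corr2 = 1.0 - b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p -= self.lr * (m / corr1) / (np.sqrt(v / corr2) + self.eps)
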