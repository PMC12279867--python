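"""Minimal dense-network machinery for the adversarial spectra generator.

Implements exactly what the three competing networks need: fully connected
layers with Leaky ReLU hidden activations, Kaiming-normal initialisation,
reverse-mode gradients written out by hand, and the second-order terms
required by the Wasserstein gradient penalty (gradient of the critic's
input-gradient norm with respect to the critic's weights).  Everything runs
in float32 numpy.

The second-order path exploits that Leaky ReLU is piecewise linear: its
activation masks are locally constant, so the penalty gradient is obtained
by reverse-mode differentiation through the (linear, per-sample) backward
recursion with the masks held fixed.  Hidden biases never enter the input
gradient and therefore receive no penalty gradient.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DTYPE = np.float32


def kaiming_normal_std(fan_in: int, leaky_slope: float) -> float:
    """Kaiming-normal std for a Leaky ReLU layer: sqrt(2 / (1 + a^2) / fan_in)."""
    gain2 = 2.0 / (1.0 + leaky_slope**2)
    return float(np.sqrt(gain2 / fan_in))


@dataclass
class MLP:
    """Fully connected net: hidden layers Leaky ReLU, configurable output activation.

    Parameters are stored as ``weights[l]`` with shape (fan_in, fan_out) and
    ``biases[l]`` with shape (fan_out,).  ``out_act`` is one of ``"linear"``
    (critic scores / classifier logits) or ``"sigmoid"`` (generator output,
    squashing synthetic reflectance into (0, 1)).
    """

    weights: list[np.ndarray]
    biases: list[np.ndarray]
    leaky_slope: float = 0.2
    out_act: str = "linear"

    @classmethod
    def init(
        cls,
        sizes: list[int],
        rng: np.random.Generator,
        leaky_slope: float = 0.2,
        out_act: str = "linear",
    ) -> "MLP":
        """Kaiming-normal weights (slope-adjusted), zero biases."""
        weights, biases = [], []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            std = kaiming_normal_std(fan_in, leaky_slope)
            weights.append(rng.normal(0.0, std, size=(fan_in, fan_out)).astype(DTYPE))
            biases.append(np.zeros(fan_out, dtype=DTYPE))
        return cls(weights, biases, leaky_slope=leaky_slope, out_act=out_act)

    @property
    def n_layers(self) -> int:
        return len(self.weights)

    def params(self) -> list[np.ndarray]:
        return list(self.weights) + list(self.biases)

    def copy(self) -> "MLP":
        return MLP(
            [w.copy() for w in self.weights],
            [b.copy() for b in self.biases],
            leaky_slope=self.leaky_slope,
            out_act=self.out_act,
        )

    # -- forward ---------------------------------------------------------

    @property
    def dtype(self) -> np.dtype:
        return self.weights[0].dtype

    def forward(self, x: np.ndarray) -> tuple[np.ndarray, dict]:
        """Return (output, cache). Cache keeps post-activations and Leaky masks."""
        dt = self.dtype
        x = np.asarray(x, dtype=dt)
        acts = [x]  # a_0 .. a_{L-1}: inputs to each layer
        masks = []  # leaky-relu derivative of each hidden pre-activation
        h = x
        for l in range(self.n_layers):
            z = h @ self.weights[l] + self.biases[l]
            if l < self.n_layers - 1:
                mask = np.where(z > 0, 1.0, self.leaky_slope).astype(dt)
                h = np.where(z > 0, z, self.leaky_slope * z).astype(dt)
                masks.append(mask)
                acts.append(h)
            else:
                if self.out_act == "sigmoid":
                    out = 1.0 / (1.0 + np.exp(-z.astype(np.float64)))
                    out = out.astype(dt)
                else:
                    out = z
        return out, {"acts": acts, "masks": masks, "out": out}

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)[0]

    # -- first-order backward -------------------------------------------

    def backward(
        self, cache: dict, grad_out: np.ndarray
    ) -> tuple[list[np.ndarray], list[np.ndarray], np.ndarray]:
        """Gradients of a scalar loss given d(loss)/d(output).

        Returns (dW list, db list, d(loss)/d(input)).
        """
        acts, masks, out = cache["acts"], cache["masks"], cache["out"]
        delta = np.asarray(grad_out, dtype=self.dtype)
        if self.out_act == "sigmoid":
            delta = delta * out * (1.0 - out)
        dWs = [None] * self.n_layers
        dbs = [None] * self.n_layers
        for l in range(self.n_layers - 1, -1, -1):
            dWs[l] = acts[l].T @ delta
            dbs[l] = delta.sum(axis=0)
            if l > 0:
                delta = (delta @ self.weights[l].T) * masks[l - 1]
            else:
                delta = delta @ self.weights[l].T
        return dWs, dbs, delta

    # -- input gradient of a scalar-output critic ------------------------

    def input_gradient(self, cache: dict) -> tuple[np.ndarray, list[np.ndarray]]:
        """Per-sample gradient of the (linear, 1-d) output w.r.t. the input.

        Also returns the intermediate reverse signals ``r_l`` needed by
        :meth:`penalty_param_grads`.  Only valid for ``out_act == "linear"``
        with output dimension 1.
        """
        if self.out_act != "linear" or self.weights[-1].shape[1] != 1:
            raise ValueError("input_gradient requires a scalar linear output")
        masks = cache["masks"]
        n = cache["acts"][0].shape[0]
        r = np.ones((n, 1), dtype=DTYPE)
        rs = [None] * self.n_layers  # rs[l] = reverse signal entering layer l
        rs[self.n_layers - 1] = r
        for l in range(self.n_layers - 1, 0, -1):
            r = (r @ self.weights[l].T) * masks[l - 1]
            rs[l - 1] = r
        g = r @ self.weights[0].T
        return g, rs

    def penalty_param_grads(
        self, cache: dict, rs: list[np.ndarray], u: np.ndarray
    ) -> tuple[list[np.ndarray], list[np.ndarray]]:
        """Weight gradients of a penalty P given u = dP/d(input gradient).

        Reverse-mode pass through the backward recursion of
        :meth:`input_gradient`, masks held fixed (exact a.e. for piecewise
        linear activations).  Biases get zero gradient.
        """
        masks = cache["masks"]
        dWs = [np.zeros_like(w) for w in self.weights]
        dbs = [np.zeros_like(b) for b in self.biases]
        # g = rs[0] @ W0^T
        t = np.asarray(u, dtype=self.dtype)
        dWs[0] += t.T @ rs[0]
        t = t @ self.weights[0]  # dP/d rs[0]
        for l in range(1, self.n_layers):
            t = t * masks[l - 1]  # through rs[l-1] = (rs[l] @ Wl^T) * mask
            dWs[l] += t.T @ rs[l]
            if l < self.n_layers - 1:
                t = t @ self.weights[l]
        return dWs, dbs


@dataclass
class Adam:
    """Adam over a list of parameter arrays; default moments follow WGAN-GP practice."""

    params: list[np.ndarray]
    lr: float = 1e-3
    beta1: float = 0.5
    beta2: float = 0.9
    eps: float = 1e-8
    m: list[np.ndarray] = field(default_factory=list)
    v: list[np.ndarray] = field(default_factory=list)
    t: int = 0

    def __post_init__(self) -> None:
        if not self.m:
            self.m = [np.zeros_like(p) for p in self.params]
            self.v = [np.zeros_like(p) for p in self.params]

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            g = g.astype(p.dtype)
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(logits: np.ndarray, label_idx: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy and its gradient w.r.t. the logits."""
    n = logits.shape[0]
    p = softmax(logits.astype(np.float64))
    picked = p[np.arange(n), label_idx]
    loss = float(-np.log(np.clip(picked, 1e-12, None)).mean())
    grad = p.copy()
    grad[np.arange(n), label_idx] -= 1.0
    return loss, (grad / n).astype(DTYPE)
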