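"""The multi-output neural corrector φ(ŷ, ω).

A single small network — one tanh hidden layer of five neurons, linear
output — maps the normalized state vector to all active correction terms at
once (output j feeds correction slot j only).  The output bias is
initialized at the slot baselines b (1 for multiplicative, 0 for additive)
with small random weights, so training starts from the unmodified
mechanistic model.

Implemented directly in numpy with analytic forward/backward passes and an
analytic input Jacobian, which the trainer's discrete adjoint and the
smoothness penalty both rely on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["NeuralCorrector"]


@dataclass
class NeuralCorrector:
    """φ(x) = gains ⊙ (W2 tanh(W1 x + b1) + b2).

    ``gains`` are fixed (non-trainable) per-output factors letting additive
    corrections reach the O(10) magnitudes a nondimensionalized rate
    equation can require without driving the trainable weights far from
    their small-initialization regime.
    """

    W1: np.ndarray  # (hidden, n_inputs)
    b1: np.ndarray  # (hidden,)
    W2: np.ndarray  # (n_outputs, hidden)
    b2: np.ndarray  # (n_outputs,)
    gains: np.ndarray  # (n_outputs,), fixed
    input_names: tuple[str, ...] = ()

    @classmethod
    def initialize(cls, n_inputs: int, baseline: np.ndarray,
                   rng: np.random.Generator, hidden: int = 5,
                   scale: float = 0.1, gains: np.ndarray | None = None,
                   input_names: tuple[str, ...] = ()) -> "NeuralCorrector":
        n_outputs = len(baseline)
        gains = (np.ones(n_outputs) if gains is None
                 else np.asarray(gains, dtype=float).copy())
        safe = np.where(gains == 0, 1.0, gains)
        return cls(
            W1=scale * rng.standard_normal((hidden, n_inputs)),
            b1=np.zeros(hidden),
            W2=scale * rng.standard_normal((n_outputs, hidden)) / safe[:, None],
            b2=np.asarray(baseline, dtype=float) / safe,
            gains=gains,
            input_names=tuple(input_names),
        )

    # -- shapes ------------------------------------------------------------

    @property
    def n_inputs(self) -> int:
        return self.W1.shape[1]

    @property
    def n_outputs(self) -> int:
        return self.W2.shape[0]

    @property
    def n_weights(self) -> int:
        return self.W1.size + self.b1.size + self.W2.size + self.b2.size

    def copy(self) -> "NeuralCorrector":
        return NeuralCorrector(self.W1.copy(), self.b1.copy(),
                               self.W2.copy(), self.b2.copy(),
                               self.gains.copy(), self.input_names)

    def drop_output(self, position: int) -> "NeuralCorrector":
        """Corrector without output ``position`` (used when a slot is pruned;
        remaining weights carry over, so refits warm-start)."""
        keep = [i for i in range(self.n_outputs) if i != position]
        return NeuralCorrector(self.W1.copy(), self.b1.copy(),
                               self.W2[keep].copy(), self.b2[keep].copy(),
                               self.gains[keep].copy(), self.input_names)

    # -- flat-vector view (optimizer state, finite-difference checks) ------

    def get_flat(self) -> np.ndarray:
        return np.concatenate([self.W1.ravel(), self.b1, self.W2.ravel(), self.b2])

    def set_flat(self, flat: np.ndarray) -> None:
        i = 0
        for arr in (self.W1, self.b1, self.W2, self.b2):
            arr[...] = flat[i:i + arr.size].reshape(arr.shape)
            i += arr.size

    def flat_grad(self, dW1, db1, dW2, db2) -> np.ndarray:
        return np.concatenate([dW1.ravel(), db1, dW2.ravel(), db2])

    # -- forward / backward ------------------------------------------------

    def forward(self, x: np.ndarray) -> np.ndarray:
        """φ(x); ``x`` has shape (..., n_inputs), output (..., n_outputs)."""
        h = np.tanh(x @ self.W1.T + self.b1)
        return (h @ self.W2.T + self.b2) * self.gains

    def forward_cached(self, x: np.ndarray):
        h = np.tanh(x @ self.W1.T + self.b1)
        return (h @ self.W2.T + self.b2) * self.gains, h

    def backward(self, x: np.ndarray, h: np.ndarray, g: np.ndarray):
        """VJP: cotangent ``g`` (..., n_outputs) → (weight grads, dx).

        Weight gradients are summed over all leading batch dimensions.
        """
        batch_axes = tuple(range(g.ndim - 1))
        g = g * self.gains
        dW2 = np.tensordot(g, h, axes=(batch_axes, batch_axes))
        db2 = g.sum(axis=batch_axes)
        gh = (g @ self.W2) * (1 - h * h)  # (..., hidden)
        dW1 = np.tensordot(gh, x, axes=(batch_axes, batch_axes))
        db1 = gh.sum(axis=batch_axes)
        dx = gh @ self.W1
        return (dW1, db1, dW2, db2), dx

    def input_jacobian(self, x: np.ndarray) -> np.ndarray:
        """∂φ/∂x, shape (..., n_outputs, n_inputs) — exact, not numeric."""
        h = np.tanh(x @ self.W1.T + self.b1)
        D = 1 - h * h  # (..., hidden)
        return np.einsum("k,ku,...u,uv->...kv", self.gains, self.W2, D, self.W1)

    # -- smoothness penalty ------------------------------------------------

    def jacobian_penalty(self, x: np.ndarray) -> float:
        """Mean over samples of Σ_{k,v} (∂φ_k/∂x_v)²."""
        J = self.input_jacobian(x)
        if J.size == 0:
            return 0.0
        return float(np.mean(np.sum(J * J, axis=(-2, -1))))

    def jacobian_penalty_grad(self, x: np.ndarray):
        """(value, weight gradients) of the mean squared input Jacobian.

        Derived analytically: with h = tanh(W1 x + b1), D = 1 - h²,
        J = W2 diag(D) W1, the per-sample gradient of Σ J² follows from the
        product rule on W2, W1 and the D(h(W1, b1)) dependence.
        """
        x2 = x.reshape(-1, self.n_inputs)
        n = x2.shape[0]
        h = np.tanh(x2 @ self.W1.T + self.b1)     # (n, H)
        D = 1 - h * h
        W2g = self.gains[:, None] * self.W2       # fold fixed gains into W2
        M = np.einsum("nu,uv->nuv", D, self.W1)   # (n, H, V)
        J = np.einsum("ku,nuv->nkv", W2g, M)      # (n, K, V)
        value = float(np.sum(J * J) / n) if J.size else 0.0

        WtJ = np.einsum("ku,nkv->nuv", W2g, J)              # (n, H, V)
        dW2 = 2 * self.gains[:, None] * np.einsum("nkv,nuv->ku", J, M) / n
        q = np.einsum("nuv,uv->nu", WtJ, self.W1)           # (n, H)
        dW1 = (2 * np.einsum("nu,nuv->uv", D, WtJ)
               - 4 * np.einsum("nu,nv->uv", h * D * q, x2)) / n
        db1 = -4 * np.einsum("nu->u", h * D * q) / n
        db2 = np.zeros_like(self.b2)
        return value, (dW1, db1, dW2, db2)
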