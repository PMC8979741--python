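"""Minimal dense-network core (ReLU MLP + Adam) shared by the GAN and the
DNN classifier.

Row-major convention: activations are (batch, width); layer ``l`` computes
``h_l = phi(h_{l-1} @ W_l + b_l)`` with ReLU on hidden layers and a
configurable output activation.  Everything is plain NumPy and fully
deterministic under a seeded Generator.
"""

from __future__ import annotations

import numpy as np

__all__ = ["MLP", "Adam"]


def _relu(z):
    return np.maximum(z, 0.0)


class MLP:
    """Fully connected network with ReLU hidden layers.

    Parameters
    ----------
    sizes : sequence of int
        Layer widths including input and output, e.g. (344, 512, 256, 128, 1).
    out_activation : {"linear", "tanh"}
        Output nonlinearity.  Sigmoid outputs are handled by the caller on
        top of a linear output (numerically stabler loss gradients).
    dropout : float
        Dropout rate applied after the **last hidden layer** during training
        passes that supply an ``rng`` (inverted dropout).
    """

    def __init__(self, sizes, rng: np.random.Generator,
                 out_activation: str = "linear", dropout: float = 0.0):
        if out_activation not in ("linear", "tanh"):
            raise ValueError(f"unsupported output activation {out_activation!r}")
        if not 0.0 <= dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        self.sizes = tuple(int(s) for s in sizes)
        self.out_activation = out_activation
        self.dropout = float(dropout)
        self.W: list[np.ndarray] = []
        self.b: list[np.ndarray] = []
        for fan_in, fan_out in zip(self.sizes[:-1], self.sizes[1:]):
            # He initialisation for the ReLU stack
            self.W.append(rng.standard_normal((fan_in, fan_out)) * np.sqrt(2.0 / fan_in))
            self.b.append(np.zeros(fan_out))

    @property
    def n_layers(self) -> int:
        return len(self.W)

    @property
    def n_parameters(self) -> int:
        return int(sum(w.size for w in self.W) + sum(b.size for b in self.b))

    def parameters(self) -> list[np.ndarray]:
        return self.W + self.b

    def forward(self, X: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None):
        """Return (output, cache).  Dropout is applied only when ``train``
        is true and an rng is supplied."""
        h = np.asarray(X, dtype=float)
        hs = [h]          # post-activation values, hs[0] = input
        masks = [None]    # ReLU masks per hidden layer (None for output)
        drop_mask = None
        L = self.n_layers
        for l in range(L):
            z = h @ self.W[l] + self.b[l]
            if l < L - 1:
                h = _relu(z)
                masks.append(z > 0)
                if (
                    train
                    and self.dropout > 0.0
                    and rng is not None
                    and l == L - 2
                ):
                    drop_mask = (
                        rng.random(h.shape) >= self.dropout
                    ) / (1.0 - self.dropout)
                    h = h * drop_mask
            else:
                if self.out_activation == "tanh":
                    h = np.tanh(z)
                else:
                    h = z
                masks.append(None)
            hs.append(h)
        cache = {"hs": hs, "masks": masks, "drop_mask": drop_mask}
        return h, cache

    def backward(self, cache, dout: np.ndarray):
        """Backprop ``dout`` (gradient w.r.t. the network output).

        Returns (dWs, dbs, dX); gradients are sums over the batch — divide
        by the batch size in the loss if a mean is wanted.
        """
        hs, masks = cache["hs"], cache["masks"]
        L = self.n_layers
        if self.out_activation == "tanh":
            delta = dout * (1.0 - hs[-1] ** 2)
        else:
            delta = np.asarray(dout, dtype=float)
        dWs = [None] * L
        dbs = [None] * L
        for l in range(L - 1, -1, -1):
            # hs[l] is the layer input as seen in forward (post-dropout for
            # the last hidden layer), so it is used as-is here.
            dWs[l] = hs[l].T @ delta
            dbs[l] = delta.sum(axis=0)
            delta = delta @ self.W[l].T
            if l == L - 1 and cache["drop_mask"] is not None:
                delta = delta * cache["drop_mask"]
            if l > 0:
                delta = delta * masks[l]
        return dWs, dbs, delta

    def input_jacobian_vectors(self, cache):
        """Per-sample gradient of a scalar output w.r.t. the input, plus the
        masked backward signals ``s_l`` needed for the gradient-penalty
        double-backprop.  Only valid for scalar-output linear-head networks.

        Returns (g, s_list): ``g`` is (batch, d_in); ``s_list[l]`` is the
        (batch, width_l) gradient of the output w.r.t. layer ``l``'s
        pre-activation, for l = 1..L (1-indexed like the layers).
        """
        if self.sizes[-1] != 1 or self.out_activation != "linear":
            raise RuntimeError("input gradients require a scalar linear output")
        masks = cache["masks"]
        L = self.n_layers
        B = cache["hs"][0].shape[0]
        s = np.ones((B, 1))
        s_list = [None] * (L + 1)
        s_list[L] = s
        for l in range(L - 1, 0, -1):
            s = (s @ self.W[l].T) * masks[l]
            s_list[l] = s
        g = s @ self.W[0].T
        return g, s_list


class Adam:
    """Adam optimiser over a list of parameter arrays (updated in place)."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
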