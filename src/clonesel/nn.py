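"""Multi-task feed-forward network trained with Adam.

Architecture: an input layer (one unit per summary statistic), a stack
of ReLU hidden layers with inverted dropout, and five output heads --
one softmax classification head over the four evolutionary classes and
four linear regression heads (one unit each) for the evolutionary
parameters.  The loss is sparse categorical cross-entropy plus the sum
of the per-head mean squared errors, with equal weights.

Implemented directly in numpy: forward pass, backpropagation, and the
Adam update are explicit, which keeps training bit-reproducible for a
fixed seed and free of framework dependencies.  The backward pass is
verified against finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class MultiTaskMLP:
    """ReLU MLP with a softmax class head and linear regression heads."""

    def __init__(
        self,
        n_in: int = 16,
        hidden: tuple[int, ...] = (512, 512, 512),
        n_classes: int = 4,
        n_reg: int = 4,
        dropout: float = 0.1,
        lr: float = 1e-3,
        seed: int = 0,
    ) -> None:
        self.n_in = n_in
        self.hidden = tuple(hidden)
        self.n_classes = n_classes
        self.n_reg = n_reg
        self.dropout = dropout
        self.lr = lr
        self.seed = seed
        rng = np.random.default_rng(seed)
        dims = [n_in, *hidden]
        self.W = [
            rng.normal(0.0, np.sqrt(2.0 / dims[i]), size=(dims[i], dims[i + 1]))
            for i in range(len(hidden))
        ]
        self.b = [np.zeros(d) for d in hidden]
        h_last = hidden[-1]
        self.Wc = rng.normal(0.0, np.sqrt(1.0 / h_last), size=(h_last, n_classes))
        self.bc = np.zeros(n_classes)
        self.Wr = rng.normal(0.0, np.sqrt(1.0 / h_last), size=(h_last, n_reg))
        self.br = np.zeros(n_reg)
        self._init_adam()

    # ---- parameter plumbing -------------------------------------------------
    def _params(self) -> list[np.ndarray]:
        return [*self.W, *self.b, self.Wc, self.bc, self.Wr, self.br]

    def _init_adam(self) -> None:
        self._m = [np.zeros_like(p) for p in self._params()]
        self._v = [np.zeros_like(p) for p in self._params()]
        self._t = 0

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self._params()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        params = self._params()
        if len(weights) != len(params):
            raise ValueError("weight list length mismatch")
        nh = len(self.W)
        self.W = [w.copy() for w in weights[:nh]]
        self.b = [w.copy() for w in weights[nh:2 * nh]]
        self.Wc, self.bc, self.Wr, self.br = (w.copy() for w in weights[2 * nh:])
        self._init_adam()

    # ---- forward / backward -------------------------------------------------
    def _forward(self, X, rng=None):
        """Return (activations, dropout masks, probs, reg)."""
        acts = [X]
        masks = []
        h = X
        for W, b in zip(self.W, self.b):
            h = np.maximum(h @ W + b, 0.0)
            if rng is not None and self.dropout > 0:
                mask = (rng.random(h.shape) >= self.dropout) / (1.0 - self.dropout)
                h = h * mask
                masks.append(mask)
            else:
                masks.append(None)
            acts.append(h)
        probs = softmax(acts[-1] @ self.Wc + self.bc)
        reg = acts[-1] @ self.Wr + self.br
        return acts, masks, probs, reg

    def loss_and_grads(self, X, y_class, Y_reg, rng=None):
        """Mean loss over the batch and gradients for every parameter."""
        B = X.shape[0]
        acts, masks, probs, reg = self._forward(X, rng)
        h_last = acts[-1]

        eps = 1e-12
        ce = -np.mean(np.log(probs[np.arange(B), y_class] + eps))
        mse = np.mean((reg - Y_reg) ** 2, axis=0)  # per head
        loss = ce + mse.sum()

        dlogits = probs.copy()
        dlogits[np.arange(B), y_class] -= 1.0
        dlogits /= B
        dreg = 2.0 * (reg - Y_reg) / B

        gWc = h_last.T @ dlogits
        gbc = dlogits.sum(axis=0)
        gWr = h_last.T @ dreg
        gbr = dreg.sum(axis=0)

        dh = dlogits @ self.Wc.T + dreg @ self.Wr.T
        gW = [None] * len(self.W)
        gb = [None] * len(self.b)
        for i in range(len(self.W) - 1, -1, -1):
            h = acts[i + 1]
            if masks[i] is not None:
                dh = dh * masks[i]
                # activation after ReLU but before dropout scaling
                relu_grad = (h > 0).astype(float)
            else:
                relu_grad = (h > 0).astype(float)
            dz = dh * relu_grad
            gW[i] = acts[i].T @ dz
            gb[i] = dz.sum(axis=0)
            dh = dz @ self.W[i].T
        return loss, [*gW, *gb, gWc, gbc, gWr, gbr]

    def _adam_step(self, grads, beta1=0.9, beta2=0.999, eps=1e-8):
        self._t += 1
        params = self._params()
        lr_t = self.lr * np.sqrt(1 - beta2**self._t) / (1 - beta1**self._t)
        for p, g, m, v in zip(params, grads, self._m, self._v):
            m *= beta1
            m += (1 - beta1) * g
            v *= beta2
            v += (1 - beta2) * g * g
            p -= lr_t * m / (np.sqrt(v) + eps)

    # ---- public API ---------------------------------------------------------
    def fit(
        self,
        X: np.ndarray,
        y_class: np.ndarray,
        Y_reg: np.ndarray,
        batch_size: int = 500,
        epochs: int = 20,
        seed: int | None = None,
    ) -> list[float]:
        """Mini-batch Adam training; returns the per-epoch mean loss."""
        rng = np.random.default_rng(self.seed + 1 if seed is None else seed)
        n = X.shape[0]
        history = []
        for _epoch in range(epochs):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, batch_size):
                idx = order[start:start + batch_size]
                loss, grads = self.loss_and_grads(
                    X[idx], y_class[idx], Y_reg[idx], rng
                )
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"non-finite training loss at epoch {_epoch}: {loss}"
                    )
                self._adam_step(grads)
                losses.append(loss)
            history.append(float(np.mean(losses)))
        return history

    def predict(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Deterministic inference (dropout off): (softmax probs, regressions)."""
        _, _, probs, reg = self._forward(np.asarray(X, dtype=float), rng=None)
        return probs, reg
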