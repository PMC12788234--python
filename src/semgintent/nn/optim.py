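"""Optimization: AdamW, plateau scheduler, and the softmax cross-entropy.

AdamW uses decoupled weight decay (the decay multiplies the parameter
directly, scaled by the learning rate, before the Adam update), matching the
convention of the deep-learning frameworks this training protocol mirrors.
"""

from __future__ import annotations

import numpy as np

from .core import Parameter

LOG_FLOOR = 1e-12  # clamp inside the cross-entropy log


class AdamW:
    def __init__(self, params: list[Parameter], lr: float = 0.003,
                 betas: tuple[float, float] = (0.9, 0.999),
                 weight_decay: float = 0.0001, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.weight_decay = weight_decay
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in params]
        self._v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.b1, self.b2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self._m, self._v):
            g = p.grad
            p.data *= 1.0 - self.lr * self.weight_decay
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0


class ReduceLROnPlateau:
    """Halve (by ``factor``) the learning rate when the monitored loss has
    not improved for more than ``patience`` epochs."""

    def __init__(self, optimizer: AdamW, factor: float = 0.5, patience: int = 5,
                 min_lr: float = 0.0):
        self.optimizer = optimizer
        self.factor = factor
        self.patience = patience
        self.min_lr = min_lr
        self.best = np.inf
        self.bad_epochs = 0

    def step(self, metric: float) -> None:
        if metric < self.best:
            self.best = metric
            self.bad_epochs = 0
        else:
            self.bad_epochs += 1
            if self.bad_epochs > self.patience:
                self.optimizer.lr = max(self.optimizer.lr * self.factor, self.min_lr)
                self.bad_epochs = 0


def softmax(scores: np.ndarray) -> np.ndarray:
    z = scores - scores.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(y_onehot: np.ndarray, probs: np.ndarray) -> float:
    """Mean cross-entropy  L = -(1/N) sum_n sum_i y_i^n log(p_i^n),
    with the log clamped at 1e-12."""
    if y_onehot.shape != probs.shape:
        raise ValueError(f"shape mismatch: y {y_onehot.shape} vs p {probs.shape}")
    logp = np.log(np.maximum(probs, LOG_FLOOR))
    return float(-(y_onehot * logp).sum() / y_onehot.shape[0])


def softmax_cross_entropy(scores: np.ndarray, y_onehot: np.ndarray
                          ) -> tuple[float, np.ndarray]:
    """Loss and gradient w.r.t. the unnormalized scores."""
    p = softmax(scores)
    loss = cross_entropy(y_onehot, p)
    dscores = (p - y_onehot) / scores.shape[0]
    return loss, dscores.astype(scores.dtype)


def averaged_probs_cross_entropy(
    scores_a: np.ndarray, scores_b: np.ndarray, y_onehot: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """Cross-entropy of equal-weight averaged softmax probabilities (the
    decision-level fusion head), with gradients for both score sets."""
    pa, pb = softmax(scores_a), softmax(scores_b)
    p = 0.5 * (pa + pb)
    loss = cross_entropy(y_onehot, p)
    dp = -(y_onehot / np.maximum(p, LOG_FLOOR)) / y_onehot.shape[0]
    da = 0.5 * pa * (dp - (dp * pa).sum(axis=-1, keepdims=True))
    db = 0.5 * pb * (dp - (dp * pb).sum(axis=-1, keepdims=True))
    return loss, da.astype(scores_a.dtype), db.astype(scores_b.dtype)
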