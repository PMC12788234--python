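"""Multi-head scaled dot-product self-attention over short token sequences.

Used by the cross-domain interaction stage: tokens are 30-dim band vectors
(one token per time step plus the temporally compressed guidance token), and
the same weights are shared across the 8 muscle channels by folding the
muscle axis into the batch axis before calling this module.
"""

from __future__ import annotations

import numpy as np

from .core import DEFAULT_DTYPE, Module
from .layers import Linear


def _softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


class MultiHeadSelfAttention(Module):
    """Self-attention on (batch, tokens, token_dim) with an output
    projection back to ``token_dim``."""

    def __init__(self, token_dim: int, d_model: int = 64, n_heads: int = 2,
                 rng=None, dtype=DEFAULT_DTYPE):
        if d_model % n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        rng = rng or np.random.default_rng(0)
        self.n_heads = n_heads
        self.d_head = d_model // n_heads
        self.q_proj = Linear(token_dim, d_model, rng=rng, dtype=dtype)
        self.k_proj = Linear(token_dim, d_model, rng=rng, dtype=dtype)
        self.v_proj = Linear(token_dim, d_model, rng=rng, dtype=dtype)
        self.out_proj = Linear(d_model, token_dim, rng=rng, dtype=dtype)

    def _split(self, x: np.ndarray) -> np.ndarray:
        m, length, _ = x.shape
        return x.reshape(m, length, self.n_heads, self.d_head).transpose(0, 2, 1, 3)

    def _merge(self, x: np.ndarray) -> np.ndarray:
        m, h, length, dh = x.shape
        return x.transpose(0, 2, 1, 3).reshape(m, length, h * dh)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        q = self._split(self.q_proj.forward(x, train))
        k = self._split(self.k_proj.forward(x, train))
        v = self._split(self.v_proj.forward(x, train))
        scale = 1.0 / np.sqrt(self.d_head)
        # softmax computed in place: the (batch, heads, L, L) score tensor is
        # the dominant allocation for long token sequences
        scores = q @ k.swapaxes(-1, -2)
        scores *= scale
        scores -= scores.max(axis=-1, keepdims=True)
        np.exp(scores, out=scores)
        scores /= scores.sum(axis=-1, keepdims=True)
        attn = scores
        ctx = attn @ v
        self._cache = (q, k, v, attn, scale)
        self.last_attention = attn  # exposed for the row-stochasticity checks
        return self.out_proj.forward(self._merge(ctx), train)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        q, k, v, attn, scale = self._cache
        dctx = self._split(self.out_proj.backward(dy))
        dattn = dctx @ v.swapaxes(-1, -2)
        dv = attn.swapaxes(-1, -2) @ dctx
        # softmax jacobian along the key axis, reusing the dattn buffer
        dattn -= (dattn * attn).sum(axis=-1, keepdims=True)
        dattn *= attn
        dattn *= scale
        dscores = dattn
        dq = dscores @ k
        dk = dscores.swapaxes(-1, -2) @ q
        dx = self.q_proj.backward(self._merge(dq))
        dx = dx + self.k_proj.backward(self._merge(dk))
        dx = dx + self.v_proj.backward(self._merge(dv))
        return dx
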