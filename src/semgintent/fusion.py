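"""Frequency-informed integration attention (IFIA) and fusion baselines.

The IFIA block sits at the stage-2 insertion point of the time-frequency
branch, where features are a (30 bands, 74 time steps, 8 muscles) block:

1. channel enhancement -- a squeeze-style MLP maps the 1192 flattened
   frequency-branch features to one logistic gate per CWT band; each band is
   multiplied by its gate, so the global spectral energy distribution decides
   which time-frequency bands to amplify;
2. temporal compression -- the gated block is averaged over time into a
   single global-modulation token per band/muscle;
3. cross-domain interaction -- per muscle channel, the 74 original time-step
   tokens (30-dim band vectors) and the compressed guidance token pass
   through multi-head self-attention; the time-step outputs are added
   residually to the original features.

Ablation variants drop one stage each; the conventional data-, feature- and
decision-level fusion baselines are assembled in
:class:`semgintent.network.IntentNetwork` and exposed here through
:func:`build_variant`.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .config import FUSION_VARIANTS, IFIAConfig, ModelConfig
from .network import IFIA_VARIANTS, IntentNetwork
from .nn import Linear, Module, MultiHeadSelfAttention, ReLU, Sequential, Sigmoid


def temporal_compress(block: np.ndarray) -> np.ndarray:
    """Mean over the time axis of a (N, bands, time, channels) block,
    keeping a singleton time axis."""
    return block.mean(axis=2, keepdims=True)


def _to_tokens(block: np.ndarray) -> np.ndarray:
    """(N, B, T, C) -> (N*C, T, B): per-muscle sequences of band vectors."""
    n, b, t, c = block.shape
    return np.ascontiguousarray(block.transpose(0, 3, 2, 1)).reshape(n * c, t, b)


def _from_tokens(tok: np.ndarray, n: int, c: int) -> np.ndarray:
    t, b = tok.shape[1], tok.shape[2]
    return np.ascontiguousarray(tok.reshape(n, c, t, b).transpose(0, 3, 2, 1))


class IFIABlock(Module):
    """Channel enhancement + cross-domain interaction at the stage-2 block.

    ``use_gate`` / ``use_attention`` / ``use_compress`` select the full
    module or one of its ablations.  ``gate_override`` is a diagnostic knob:
    when set to an array broadcastable to the gate shape, it replaces the
    learned gates (used to verify that unit gates without attention reduce
    fusion to the identity).
    """

    def __init__(self, mcfg: ModelConfig, icfg: IFIAConfig,
                 use_gate: bool = True, use_attention: bool = True,
                 use_compress: bool = True, rng=None):
        rng = rng or np.random.default_rng(0)
        self.n_bands = mcfg.n_scales
        self.n_channels = mcfg.n_channels
        self.use_gate = use_gate
        self.use_attention = use_attention
        self.use_compress = use_compress
        self.gate_override: np.ndarray | None = None
        freq_width = mcfg.n_channels * (
            (mcfg.spectrum_bins - 2 * (mcfg.per_band_kernel - 1)) // mcfg.pool_size
        )
        if use_gate:
            hidden = freq_width // icfg.r
            if hidden < 1:
                raise ValueError(
                    f"reduction ratio r={icfg.r} collapses the gating MLP "
                    f"hidden width to zero (input width {freq_width})"
                )
            self.mlp = Sequential(
                Linear(freq_width, hidden, rng=rng),
                ReLU(),
                Linear(hidden, self.n_bands, rng=rng),
                Sigmoid(),
            )
        if use_attention:
            self.attn = MultiHeadSelfAttention(
                self.n_bands, d_model=icfg.d_model, n_heads=icfg.n_heads, rng=rng
            )

    # -- spec-level operations ----------------------------------------------
    def channel_enhance(self, block: np.ndarray, freq_flat: np.ndarray,
                        train: bool = False) -> tuple[np.ndarray, np.ndarray]:
        """Gate each band of the block by logistic(MLP(frequency features))."""
        gates = self.mlp.forward(freq_flat, train)  # (N, bands)
        if self.gate_override is not None:
            gates = np.broadcast_to(
                np.asarray(self.gate_override, dtype=block.dtype),
                gates.shape,
            )
        return block * gates[:, :, None, None], gates

    def cross_interact(self, original: np.ndarray, guide: np.ndarray,
                       train: bool = False) -> np.ndarray:
        """Attend over [original time steps + guidance token(s)] per muscle
        channel; outputs for the original steps are added residually."""
        n, _, t, c = original.shape
        tokens = np.concatenate([_to_tokens(original), _to_tokens(guide)], axis=1)
        out = self.attn.forward(tokens, train)
        return original + _from_tokens(out[:, :t], n, c)

    # -- fused forward/backward ----------------------------------------------
    def forward(self, block: np.ndarray, freq_flat: np.ndarray,
                train: bool = False) -> np.ndarray:
        self._n, _, self._t, self._c = block.shape
        self._block = block
        if self.use_gate:
            gated, gates = self.channel_enhance(block, freq_flat, train)
            self._gates = gates
        else:
            gated, self._gates = block, None
        if not self.use_attention:
            return gated
        guide = temporal_compress(gated) if self.use_compress else gated
        self._guide_len = guide.shape[2]
        tokens = np.concatenate([_to_tokens(block), _to_tokens(guide)], axis=1)
        out = self.attn.forward(tokens, train)
        return block + _from_tokens(out[:, : self._t], n=self._n, c=self._c)

    def _gate_backward(self, dgated: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Gradient through the gating product; returns (dblock, dfreq)."""
        gates = self._gates
        dblock = dgated * gates[:, :, None, None]
        dgates = (dgated * self._block).sum(axis=(2, 3))
        dfreq = self.mlp.backward(dgates.astype(dgated.dtype))
        return dblock, dfreq

    def backward(self, dfused: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        n, t, c = self._n, self._t, self._c
        zero_freq = np.zeros((n, 0))
        if not self.use_attention:
            if self.use_gate and self.gate_override is None:
                return self._gate_backward(dfused)
            return dfused, zero_freq

        dx = dfused.copy()  # residual path
        dout = np.zeros(
            (n * c, t + self._guide_len, self.n_bands), dtype=dfused.dtype
        )
        dout[:, :t] = _to_tokens(dfused)
        dtokens = self.attn.backward(dout)
        dx += _from_tokens(dtokens[:, :t], n, c)
        dguide = _from_tokens(dtokens[:, t:], n, c)
        if self.use_compress:
            dgated = np.broadcast_to(dguide / t, (n, self.n_bands, t, c)).astype(
                dfused.dtype
            )
        else:
            dgated = dguide
        if self.use_gate and self.gate_override is None:
            dblock, dfreq = self._gate_backward(dgated)
            return dx + dblock, dfreq
        return dx + dgated, zero_freq


_IFIA_FLAGS = {
    "ifia_full": dict(use_gate=True, use_attention=True, use_compress=True),
    "no_channel_attention": dict(use_gate=False, use_attention=True, use_compress=True),
    "no_cross_interaction": dict(use_gate=True, use_attention=False, use_compress=True),
    "no_temporal_compression": dict(use_gate=True, use_attention=True, use_compress=False),
}


def build_variant(name: str, mcfg: ModelConfig, icfg: IFIAConfig | None = None,
                  seed: int = 0) -> IntentNetwork:
    """Assemble a classifier for one fusion variant name.

    Names: baseline, ifia_full, no_channel_attention, no_cross_interaction,
    no_temporal_compression, data_level, feature_level, decision_level.
    """
    if name not in FUSION_VARIANTS:
        raise ValueError(
            f"unknown fusion variant {name!r}; expected one of {FUSION_VARIANTS}"
        )
    cfg = mcfg if mcfg.fusion_mode == name else dataclasses.replace(mcfg, fusion_mode=name)
    rng = np.random.default_rng(seed)
    block = None
    if name in IFIA_VARIANTS:
        block = IFIABlock(cfg, icfg or IFIAConfig(), rng=rng, **_IFIA_FLAGS[name])
    return IntentNetwork(cfg, rng=rng, fusion_block=block)
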