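"""CNN-TCN encoder/decoder for motion-intent recognition.

Data path (time-frequency branch): a (30, 1200, 8) scalogram passes three
frequency-partitioned stages of [per-band 3x1 temporal conv -> 4x1 average
pool], shrinking time 1200 -> 299 -> 74 -> 18; an aggregation conv mixes the
30 bands into 16 features over 16 time steps, and the result is rearranged
into a length-16 sequence of 16x8 = 128 features.  A three-block dilated
causal TCN (channels 128-256-128, dilations 1/2/4) models temporal
dependencies, and a BatchNorm -> 32-dim embedding -> dropout -> linear head
produces the class scores.  The frequency branch condenses the 601-bin FFT
magnitudes into 1192 features used by the fusion variants.

The stage-2 intermediate (30, 74, 8) is the insertion point for the
frequency-informed fusion block (see :mod:`semgintent.fusion`).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .config import IFIAConfig, ModelConfig, config_json
from .nn import (
    BandMixConv,
    BatchNorm,
    CausalConv1d,
    Dropout,
    LeakyReLU,
    Linear,
    MaxPoolTime,
    Module,
    PerBandConv,
    PerBandConvPool,
    PointwiseConv1d,
    ReLU,
    softmax,
)

IFIA_VARIANTS = (
    "ifia_full",
    "no_channel_attention",
    "no_cross_interaction",
    "no_temporal_compression",
)


def _ladder(window_samples: int, kernel: int, pool: int) -> list[int]:
    """Per-band time extents through the three conv+pool stages."""
    t = window_samples
    steps = [t]
    for _ in range(3):
        t = t - kernel + 1
        steps.append(t)
        t = t // pool
        steps.append(t)
    return steps  # e.g. [1200, 1198, 299, 297, 74, 72, 18]


class TimeFreqBranch(Module):
    """Frequency-partitioned convolutional stages plus band aggregation.

    ``forward_to_stage2`` / ``forward_from_stage2`` split the branch at the
    fusion insertion point (after the second conv+pool)."""

    def __init__(self, cfg: ModelConfig, bands: int | None = None, rng=None):
        rng = rng or np.random.default_rng(0)
        self.bands = bands if bands is not None else cfg.n_scales
        k, p = cfg.per_band_kernel, cfg.pool_size
        self.stage1 = PerBandConvPool(self.bands, k, p, rng=rng)
        self.stage2 = PerBandConvPool(self.bands, k, p, rng=rng)
        self.stage3 = PerBandConvPool(self.bands, k, p, rng=rng)
        self.agg = BandMixConv(self.bands, cfg.agg_out_channels, k, rng=rng)
        self.bn = BatchNorm(cfg.agg_out_channels)
        self.act = LeakyReLU(cfg.leaky_slope)
        self._cfg = cfg
        self._steps = _ladder(cfg.window_samples, k, p)
        self.last_shapes: dict[str, tuple[int, ...]] = {}

    def _check(self, stage: str, x: np.ndarray, t_expected: int) -> None:
        self.last_shapes[stage] = x.shape[1:]
        if x.shape[2] != t_expected:
            raise ValueError(
                f"shape ladder violated at stage {stage!r}: time extent "
                f"{x.shape[2]}, expected {t_expected}"
            )

    def forward_to_stage2(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        cfg = self._cfg
        if x.ndim != 4 or x.shape[1] != self.bands or x.shape[3] != cfg.n_channels:
            raise ValueError(
                f"input must be (N, {self.bands}, {cfg.window_samples}, "
                f"{cfg.n_channels}), got {x.shape}"
            )
        self._check("input", x, self._steps[0])
        h = self.stage1.forward(x, train)
        self._check("pool1", h, self._steps[2])
        h = self.stage2.forward(h, train)
        self._check("pool2", h, self._steps[4])
        return h

    def forward_from_stage2(self, h: np.ndarray, train: bool = False) -> np.ndarray:
        cfg = self._cfg
        h = self.stage3.forward(h, train)
        self._check("pool3", h, self._steps[6])
        h = self.agg.forward(h, train)
        self._check("agg", h, self._steps[6] - cfg.per_band_kernel + 1)
        h = self.bn.forward(h, train)
        h = self.act.forward(h, train)
        n, f, t, c = h.shape
        # rearrange (T, F x C): time-major, feature index = agg_channel*8 + muscle
        return h.transpose(0, 2, 1, 3).reshape(n, t, f * c)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return self.forward_from_stage2(self.forward_to_stage2(x, train), train)

    def backward_from_stage2(self, dseq: np.ndarray) -> np.ndarray:
        n, t, fc = dseq.shape
        f = self._cfg.agg_out_channels
        c = self._cfg.n_channels
        dh = dseq.reshape(n, t, f, c).transpose(0, 2, 1, 3)
        dh = self.act.backward(dh)
        dh = self.bn.backward(dh)
        dh = self.agg.backward(dh)
        return self.stage3.backward(dh)

    def backward_to_input(self, dstage2: np.ndarray) -> np.ndarray:
        return self.stage1.backward(self.stage2.backward(dstage2))

    def backward(self, dseq: np.ndarray) -> np.ndarray:
        return self.backward_to_input(self.backward_from_stage2(dseq))

    def probe_ladder(self, x: np.ndarray) -> dict[str, tuple[int, ...]]:
        """Run the three stages unfused (explicit conv then pool) and return
        every intermediate shape, including the pre-pool conv outputs; also
        verifies the fused stages compute the same pooled values."""
        shapes: dict[str, tuple[int, ...]] = {"input": x.shape[1:]}
        h = x
        for i, stage in enumerate((self.stage1, self.stage2, self.stage3), start=1):
            conv_out, pooled = stage.forward_unfused(h)
            fused = stage.forward(h)
            if not np.allclose(fused, pooled, atol=1e-4):
                raise AssertionError(f"fused stage {i} diverges from conv+pool")
            shapes[f"conv{i}"] = conv_out.shape[1:]
            shapes[f"pool{i}"] = pooled.shape[1:]
            h = pooled
        a = self.agg.forward(h)
        shapes["agg"] = a.shape[1:]
        a = self.act.forward(self.bn.forward(a))
        n, f, t, c = a.shape
        shapes["flatten"] = (t, f * c)
        return shapes


class FreqBranch(Module):
    """Two shared 3x1 convolutions along frequency plus 4x1 max pooling:
    (601, 8) -> (149, 8); flattened width 8*149 = 1192."""

    def __init__(self, cfg: ModelConfig, rng=None):
        rng = rng or np.random.default_rng(0)
        self.conv1 = PerBandConv(1, cfg.per_band_kernel, rng=rng)
        self.conv2 = PerBandConv(1, cfg.per_band_kernel, rng=rng)
        self.pool = MaxPoolTime(cfg.pool_size)
        self._cfg = cfg
        self.last_shapes: dict[str, tuple[int, ...]] = {}

    def forward(self, spec: np.ndarray, train: bool = False) -> np.ndarray:
        cfg = self._cfg
        if spec.ndim != 3 or spec.shape[1] != cfg.spectrum_bins:
            raise ValueError(
                f"spectrum must be (N, {cfg.spectrum_bins}, {cfg.n_channels}), "
                f"got {spec.shape}"
            )
        self.last_shapes["input"] = spec.shape[1:]
        h = spec[:, None, :, :]  # single 'band'
        h = self.conv1.forward(h, train)
        self.last_shapes["conv1"] = (h.shape[2], h.shape[3])
        h = self.conv2.forward(h, train)
        self.last_shapes["conv2"] = (h.shape[2], h.shape[3])
        h = self.pool.forward(h[:, 0], train)  # (N, 149, 8)
        self.last_shapes["pool"] = h.shape[1:]
        return h

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dh = self.pool.backward(dy)[:, None, :, :]
        dh = self.conv2.backward(dh)
        dh = self.conv1.backward(dh)
        return dh[:, 0]

    @staticmethod
    def flatten(block: np.ndarray) -> np.ndarray:
        return block.reshape(block.shape[0], -1)


class TemporalBlock(Module):
    """Two causal dilated convolutions (BatchNorm + ReLU after each) with a
    residual connection; a 1x1 conv matches widths when they differ.  No
    activation follows the residual sum, so zeroed weights reduce the block
    to its residual path."""

    def __init__(self, c_in: int, c_out: int, kernel: int, dilation: int, rng=None):
        rng = rng or np.random.default_rng(0)
        self.conv1 = CausalConv1d(c_in, c_out, kernel, dilation, rng=rng)
        self.bn1 = BatchNorm(c_out)
        self.act1 = ReLU()
        self.conv2 = CausalConv1d(c_out, c_out, kernel, dilation, rng=rng)
        self.bn2 = BatchNorm(c_out)
        self.act2 = ReLU()
        self.downsample = PointwiseConv1d(c_in, c_out, rng=rng) if c_in != c_out else None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        h = self.act1.forward(self.bn1.forward(self.conv1.forward(x, train), train), train)
        h = self.act2.forward(self.bn2.forward(self.conv2.forward(h, train), train), train)
        res = self.downsample.forward(x, train) if self.downsample else x
        return h + res

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dh = self.conv2.backward(self.bn2.backward(self.act2.backward(dy)))
        dx = self.conv1.backward(self.bn1.backward(self.act1.backward(dh)))
        dx = dx + (self.downsample.backward(dy) if self.downsample else dy)
        return dx


class TCN(Module):
    """Stack of temporal blocks on (N, features, time) sequences."""

    def __init__(self, cfg: ModelConfig, rng=None):
        rng = rng or np.random.default_rng(0)
        widths = (cfg.seq_features,) + cfg.tcn_channels
        self.blocks = [
            TemporalBlock(widths[i], widths[i + 1], cfg.tcn_kernel, d, rng=rng)
            for i, d in enumerate(cfg.tcn_dilations)
        ]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if x.shape[2] < 1:
            raise ValueError("sequence length must be >= 1")
        for b in self.blocks:
            x = b.forward(x, train)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for b in reversed(self.blocks):
            dy = b.backward(dy)
        return dy


class Decoder(Module):
    """BatchNorm -> 32-dim embedding -> LeakyReLU -> dropout -> class scores."""

    def __init__(self, f_in: int, cfg: ModelConfig, rng=None):
        rng = rng or np.random.default_rng(0)
        self.bn = BatchNorm(f_in)
        self.fc1 = Linear(f_in, cfg.embed_dim, rng=rng)
        self.act = LeakyReLU(cfg.leaky_slope)
        self.drop = Dropout(cfg.dropout_p)
        self.fc2 = Linear(cfg.embed_dim, cfg.n_classes, rng=rng)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        h = self.bn.forward(x, train)
        h = self.act.forward(self.fc1.forward(h, train), train)
        h = self.drop.forward(h, train)
        return self.fc2.forward(h, train)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dh = self.drop.backward(self.fc2.backward(dy))
        dh = self.fc1.backward(self.act.backward(dh))
        return self.bn.backward(dh)


def receptive_field(cfg: ModelConfig) -> int:
    """Closed-form temporal receptive field of the TCN in time steps:
    1 + sum over all conv layers of (kernel-1)*dilation (two convs per
    block)."""
    return 1 + sum(2 * (cfg.tcn_kernel - 1) * d for d in cfg.tcn_dilations)


def _resample_indices(n_in: int, n_out: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    pos = np.linspace(0, n_in - 1, n_out)
    i0 = np.floor(pos).astype(int)
    i1 = np.minimum(i0 + 1, n_in - 1)
    w = (pos - i0).astype(np.float32)
    return i0, i1, w


class IntentNetwork(Module):
    """Full classifier assembled for one fusion variant.

    forward() consumes a batch of scalograms (N, 30, W, 8) and spectra
    (N, 601, 8) and returns unnormalized class scores; the decision-level
    variant returns a pair of score sets (one per sub-network) that the loss
    and predict_proba combine by probability averaging.
    """

    def __init__(self, cfg: ModelConfig, rng=None, fusion_block=None):
        rng = rng or np.random.default_rng(0)
        self.cfg = cfg
        self.variant = cfg.fusion_mode
        flat = cfg.seq_len * cfg.tcn_channels[-1]

        if self.variant in IFIA_VARIANTS and fusion_block is None:
            raise ValueError(f"variant {self.variant!r} requires a fusion block")
        self.fusion = fusion_block

        bands = cfg.n_scales + 1 if self.variant == "data_level" else cfg.n_scales
        self.tf_branch = TimeFreqBranch(cfg, bands=bands, rng=rng)
        self.tcn = TCN(cfg, rng=rng)

        needs_freq = self.variant in IFIA_VARIANTS + ("feature_level", "decision_level")
        self.freq_branch = FreqBranch(cfg, rng=rng) if needs_freq else None
        freq_flat = cfg.n_channels * ((cfg.spectrum_bins - 2 * (cfg.per_band_kernel - 1))
                                      // cfg.pool_size)

        if self.variant == "feature_level":
            self.decoder = Decoder(flat + freq_flat, cfg, rng=rng)
        else:
            self.decoder = Decoder(flat, cfg, rng=rng)

        if self.variant == "decision_level":
            self.freq_embed = Linear(freq_flat, cfg.seq_len * cfg.seq_features, rng=rng)
            self.freq_tcn = TCN(cfg, rng=rng)
            self.freq_decoder = Decoder(flat, cfg, rng=rng)

        self._rs = _resample_indices(cfg.spectrum_bins, cfg.window_samples)

    # -- dropout rng plumbing ------------------------------------------------
    def set_rng(self, rng: np.random.Generator) -> None:
        self.decoder.drop.set_rng(rng)
        if self.variant == "decision_level":
            self.freq_decoder.drop.set_rng(rng)

    # -- forward -------------------------------------------------------------
    def _data_level_input(self, tf: np.ndarray, spec: np.ndarray) -> np.ndarray:
        i0, i1, w = self._rs
        band = (1 - w)[None, :, None] * spec[:, i0, :] + w[None, :, None] * spec[:, i1, :]
        return np.concatenate([tf, band[:, None, :, :]], axis=1)

    def forward(self, tf: np.ndarray, spec: np.ndarray | None = None,
                train: bool = False):
        v = self.variant
        if v == "data_level":
            if spec is None:
                raise ValueError("data_level fusion needs the spectrum input")
            x = self._data_level_input(tf, spec)
            seq = self.tf_branch.forward(x, train)
        elif v in IFIA_VARIANTS:
            if spec is None:
                raise ValueError("IFIA variants need the spectrum input")
            stage2 = self.tf_branch.forward_to_stage2(tf, train)
            freq_flat = FreqBranch.flatten(self.freq_branch.forward(spec, train))
            fused = self.fusion.forward(stage2, freq_flat, train)
            seq = self.tf_branch.forward_from_stage2(fused, train)
        else:
            seq = self.tf_branch.forward(tf, train)

        enc = self.tcn.forward(seq.transpose(0, 2, 1), train)
        flat = enc.transpose(0, 2, 1).reshape(enc.shape[0], -1)

        if v == "feature_level":
            freq_flat = FreqBranch.flatten(self.freq_branch.forward(spec, train))
            self._split = flat.shape[1]
            scores = self.decoder.forward(np.concatenate([flat, freq_flat], axis=1), train)
            return scores
        if v == "decision_level":
            scores_a = self.decoder.forward(flat, train)
            freq_flat = FreqBranch.flatten(self.freq_branch.forward(spec, train))
            femb = self.freq_embed.forward(freq_flat, train)
            fseq = femb.reshape(femb.shape[0], self.cfg.seq_len, -1).transpose(0, 2, 1)
            fenc = self.freq_tcn.forward(fseq, train)
            fflat = fenc.transpose(0, 2, 1).reshape(fenc.shape[0], -1)
            scores_b = self.freq_decoder.forward(fflat, train)
            return scores_a, scores_b
        return self.decoder.forward(flat, train)

    # -- backward ------------------------------------------------------------
    def _backward_trunk(self, dflat: np.ndarray) -> np.ndarray:
        n = dflat.shape[0]
        t = self.cfg.seq_len
        denc = dflat.reshape(n, t, -1).transpose(0, 2, 1)
        dseq = self.tcn.backward(denc).transpose(0, 2, 1)
        v = self.variant
        if v in IFIA_VARIANTS:
            dstage2 = self.tf_branch.backward_from_stage2(dseq)
            dtf_stage2, dfreq_flat = self.fusion.backward(dstage2)
            if dfreq_flat.size:  # variants without gating have no freq gradient
                self.freq_branch.backward(
                    dfreq_flat.reshape(dfreq_flat.shape[0], -1, self.cfg.n_channels)
                )
            return self.tf_branch.backward_to_input(dtf_stage2)
        return self.tf_branch.backward(dseq)

    def backward(self, dscores) -> None:
        v = self.variant
        if v == "decision_level":
            da, db = dscores
            dflat = self.decoder.backward(da)
            self._backward_trunk(dflat)
            dfflat = self.freq_decoder.backward(db)
            n = dfflat.shape[0]
            dfenc = dfflat.reshape(n, self.cfg.seq_len, -1).transpose(0, 2, 1)
            dfseq = self.freq_tcn.backward(dfenc)
            dfemb = dfseq.transpose(0, 2, 1).reshape(n, -1)
            dfreq_flat = self.freq_embed.backward(dfemb)
            self.freq_branch.backward(
                dfreq_flat.reshape(n, -1, self.cfg.n_channels)
            )
            return
        dfull = self.decoder.backward(dscores)
        if v == "feature_level":
            dflat, dfreq_flat = dfull[:, : self._split], dfull[:, self._split:]
            self.freq_branch.backward(
                dfreq_flat.reshape(dfreq_flat.shape[0], -1, self.cfg.n_channels)
            )
        else:
            dflat = dfull
        self._backward_trunk(dflat)

    # -- inference -----------------------------------------------------------
    def predict_proba(self, tf: np.ndarray, spec: np.ndarray | None = None) -> np.ndarray:
        out = self.forward(tf, spec, train=False)
        if isinstance(out, tuple):
            return 0.5 * (softmax(out[0]) + softmax(out[1]))
        return softmax(out)


def count_parameters(model: Module) -> int:
    """Trainable scalars (running statistics excluded)."""
    return model.n_parameters()


# -- checkpointing ----------------------------------------------------------

def save_checkpoint(model: IntentNetwork, path: str | Path,
                    ifia_cfg: IFIAConfig | None = None) -> None:
    meta = {"model": config_json(model.cfg)}
    if ifia_cfg is not None:
        meta["ifia"] = config_json(ifia_cfg)
    arrays = {f"param/{k}": v for k, v in model.state_dict().items()}
    np.savez(path, __meta__=np.array(json.dumps(meta)), **arrays)


def load_checkpoint(model: IntentNetwork, path: str | Path,
                    ifia_cfg: IFIAConfig | None = None) -> None:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["__meta__"]))
        expected = {"model": config_json(model.cfg)}
        if ifia_cfg is not None:
            expected["ifia"] = config_json(ifia_cfg)
        if meta != expected:
            raise ValueError(
                "checkpoint config mismatch: stored "
                f"{meta} vs expected {expected}"
            )
        state = {k[len("param/"):]: data[k] for k in data.files if k.startswith("param/")}
    model.load_state_dict(state)
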