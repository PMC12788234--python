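"""Encoder/decoder architecture: shape ladder, parameter accounting,
causality, receptive field, checkpointing."""

import dataclasses

import numpy as np
import pytest

from semgintent.config import IFIAConfig, ModelConfig
from semgintent.fusion import build_variant
from semgintent.network import (
    Decoder,
    FreqBranch,
    IntentNetwork,
    TCN,
    TimeFreqBranch,
    count_parameters,
    load_checkpoint,
    receptive_field,
    save_checkpoint,
)

CFG = ModelConfig()
RNG = np.random.default_rng(5)


@pytest.fixture(scope="module")
def tf_batch():
    return RNG.standard_normal((2, 30, 1200, 8)).astype(np.float32)


@pytest.fixture(scope="module")
def spec_batch():
    return np.abs(RNG.standard_normal((2, 601, 8))).astype(np.float32)


class TestShapeLadder:
    def test_every_printed_intermediate_dimension(self, tf_batch):
        branch = TimeFreqBranch(CFG, rng=np.random.default_rng(0))
        shapes = branch.probe_ladder(tf_batch)
        assert shapes["input"] == (30, 1200, 8)
        assert shapes["conv1"] == (30, 1198, 8)
        assert shapes["pool1"] == (30, 299, 8)
        assert shapes["conv2"] == (30, 297, 8)
        assert shapes["pool2"] == (30, 74, 8)
        assert shapes["conv3"] == (30, 72, 8)
        assert shapes["pool3"] == (30, 18, 8)
        assert shapes["agg"] == (16, 16, 8)
        assert shapes["flatten"] == (16, 128)

    def test_frequency_block_ladder(self, spec_batch):
        branch = FreqBranch(CFG, rng=np.random.default_rng(0))
        out = branch.forward(spec_batch)
        assert branch.last_shapes["input"] == (601, 8)
        assert branch.last_shapes["conv1"] == (599, 8)
        assert branch.last_shapes["conv2"] == (597, 8)
        assert out.shape == (2, 149, 8)
        assert FreqBranch.flatten(out).shape == (2, 1192)

    def test_wrong_input_rejected_with_stage_name(self):
        branch = TimeFreqBranch(CFG, rng=np.random.default_rng(0))
        with pytest.raises(ValueError, match="stage 'input'"):
            branch.forward(np.zeros((2, 30, 1000, 8), dtype=np.float32))
        with pytest.raises(ValueError, match="input must be"):
            branch.forward(np.zeros((2, 29, 1200, 8), dtype=np.float32))

    def test_encoded_sequence_is_16_by_128(self, tf_batch):
        branch = TimeFreqBranch(CFG, rng=np.random.default_rng(0))
        seq = branch.forward(tf_batch)
        assert seq.shape == (2, 16, 128)
        stage2 = branch.forward_to_stage2(tf_batch)
        assert stage2.shape == (2, 30, 74, 8)


class TestParameterCounts:
    def test_branch_subcounts_decompose_baseline(self):
        net = build_variant("baseline", CFG, seed=0)
        assert net.tf_branch.n_parameters() == 1848
        assert net.tcn.n_parameters() == 609_664
        assert net.decoder.n_parameters() == 70_225
        assert count_parameters(net) == 681_737
        assert 1848 + 609_664 + 70_225 == 681_737

    def test_frequency_branch_has_8_parameters(self):
        assert FreqBranch(CFG).n_parameters() == 8

    def test_data_level_delta_is_60(self):
        base = count_parameters(build_variant("baseline", CFG, seed=0))
        data = count_parameters(build_variant("data_level", CFG, seed=0))
        assert data - base == 60
        assert data == 681_797

    def test_fusion_parameter_ordering(self):
        counts = {
            v: count_parameters(build_variant(v, CFG, IFIAConfig(), seed=0))
            for v in ("baseline", "data_level", "feature_level", "ifia_full",
                      "decision_level")
        }
        assert (counts["baseline"] <= counts["data_level"]
                < counts["feature_level"] < counts["ifia_full"]
                < counts["decision_level"])

    def test_single_affine_map_10_to_5(self):
        from semgintent.nn import Linear

        assert Linear(10, 5).n_parameters() == 55


class TestTCN:
    def test_preserves_16_by_128(self):
        tcn = TCN(CFG, rng=np.random.default_rng(0))
        x = RNG.standard_normal((2, 128, 16)).astype(np.float32)
        assert tcn.forward(x).shape == (2, 128, 16)

    def test_causality_last_step_perturbation(self):
        tcn = TCN(CFG, rng=np.random.default_rng(0))
        x = RNG.standard_normal((1, 128, 16)).astype(np.float32)
        y = tcn.forward(x)
        x2 = x.copy()
        x2[:, :, -1] += 10.0
        y2 = tcn.forward(x2)
        np.testing.assert_allclose(y[:, :, :15], y2[:, :, :15], atol=1e-5)
        assert np.abs(y[:, :, 15] - y2[:, :, 15]).max() > 1e-3

    def test_residual_identity_when_weights_zeroed(self):
        tcn = TCN(CFG, rng=np.random.default_rng(0))
        block = tcn.blocks[0]  # 128 -> 128, identity residual
        for mod in (block.conv1, block.conv2):
            mod.weight.data[...] = 0
            mod.bias.data[...] = 0
        for bn in (block.bn1, block.bn2):
            bn.gamma.data[...] = 0
            bn.beta.data[...] = 0
        x = RNG.standard_normal((2, 128, 16)).astype(np.float32)
        np.testing.assert_allclose(block.forward(x), x, atol=1e-6)

    def test_per_layer_block_counts(self):
        tcn = TCN(CFG, rng=np.random.default_rng(0))
        counts = [b.n_parameters() for b in tcn.blocks]
        assert counts == [99_072, 329_472, 181_120]


class TestReceptiveField:
    def test_default_config_covers_sequence(self):
        rf = receptive_field(CFG)
        assert rf == 29
        assert rf >= CFG.seq_len == 16

    def test_single_block_single_conv_equivalent(self):
        cfg = dataclasses.replace(CFG, tcn_dilations=(1,), tcn_channels=(128,))
        # two convs per block: 1 + 2*(3-1)*1 = 5; a single conv contributes 3
        assert receptive_field(cfg) == 5
        assert 1 + (cfg.tcn_kernel - 1) * 1 == 3

    def test_doubling_dilations_strictly_increases(self):
        cfg2 = dataclasses.replace(CFG, tcn_dilations=(2, 4, 8))
        assert receptive_field(cfg2) > receptive_field(CFG)


class TestDecoder:
    def test_score_vector_length_17(self):
        dec = Decoder(2048, CFG, rng=np.random.default_rng(0))
        x = RNG.standard_normal((3, 2048)).astype(np.float32)
        assert dec.forward(x).shape == (3, 17)

    def test_eval_mode_is_deterministic_despite_dropout(self):
        dec = Decoder(2048, dataclasses.replace(CFG, dropout_p=0.5),
                      rng=np.random.default_rng(0))
        x = RNG.standard_normal((3, 2048)).astype(np.float32)
        np.testing.assert_array_equal(dec.forward(x, train=False),
                                      dec.forward(x, train=False))

    def test_n_classes_below_2_rejected(self):
        with pytest.raises(ValueError, match="n_classes"):
            dataclasses.replace(CFG, n_classes=1)


class TestStructuralProperties:
    def test_zero_input_gives_channel_identical_columns(self, tiny_model_config):
        net = build_variant("baseline", tiny_model_config, seed=0)
        x = np.zeros((2, 5, 320, 3), dtype=np.float32)
        seq = net.tf_branch.forward(x)
        # per-band convs act along time only, so all muscle columns see the
        # same bias response
        block = seq.reshape(2, 2, tiny_model_config.agg_out_channels, 3)
        np.testing.assert_allclose(block[..., 0], block[..., 1], atol=1e-6)

    def test_muscle_column_permutation_equivariance(self, tiny_model_config):
        net = build_variant("baseline", tiny_model_config, seed=0)
        x = RNG.standard_normal((2, 5, 320, 3)).astype(np.float32)
        perm = np.array([2, 0, 1])
        a = net.tf_branch.forward(x[..., perm])
        b = net.tf_branch.forward(x)
        n, t, fc = b.shape
        b_block = b.reshape(n, t, -1, 3)[..., perm].reshape(n, t, fc)
        np.testing.assert_allclose(a, b_block, atol=1e-5)


class TestCheckpoint:
    def test_round_trip(self, tiny_model_config, tmp_path):
        net = build_variant("baseline", tiny_model_config, seed=3)
        path = tmp_path / "ckpt.npz"
        save_checkpoint(net, path)
        net2 = build_variant("baseline", tiny_model_config, seed=99)
        load_checkpoint(net2, path)
        x = RNG.standard_normal((2, 5, 320, 3)).astype(np.float32)
        np.testing.assert_array_equal(net.forward(x), net2.forward(x))

    def test_mismatched_config_fails_loudly(self, tiny_model_config, tmp_path):
        net = build_variant("baseline", tiny_model_config, seed=3)
        path = tmp_path / "ckpt.npz"
        save_checkpoint(net, path)
        other = dataclasses.replace(tiny_model_config, dropout_p=0.5)
        net2 = build_variant("baseline", other, seed=3)
        with pytest.raises(ValueError, match="config mismatch"):
            load_checkpoint(net2, path)


def test_unknown_fusion_mode_rejected():
    with pytest.raises(ValueError, match="unknown fusion_mode"):
        dataclasses.replace(CFG, fusion_mode="bogus")


def test_intent_network_requires_fusion_block_for_ifia():
    with pytest.raises(ValueError, match="requires a fusion block"):
        IntentNetwork(dataclasses.replace(CFG, fusion_mode="ifia_full"))
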