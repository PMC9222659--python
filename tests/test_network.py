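import dataclasses

import numpy as np
import pytest

from medfuse._autodiff import Tensor
from medfuse.network import (
    NetConfig,
    as_tensors,
    channel_attention,
    decode,
    decode_forward,
    encode,
    encode_forward,
    init_weights,
    load_weights,
    ma_block,
    mc_block,
    save_weights,
    spatial_attention,
)


class TestNetConfig:
    def test_defaults_are_consistent(self):
        cfg = NetConfig()
        assert cfg.encoder_out_channels == 4 * cfg.branch_channels == 240
        assert len(cfg.decoder_channels) == 5

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            NetConfig(encoder_out_channels=200)
        with pytest.raises(ValueError):
            NetConfig(reduction=7)
        with pytest.raises(ValueError):
            NetConfig(decoder_channels=(240, 64, 1))
        with pytest.raises(ValueError):
            NetConfig(dense_variant="res3")


@pytest.mark.parametrize("shape", [(17, 23), (16, 16)])
def test_spatial_dims_preserved_odd_and_even(small_cfg, small_weights, shape, rng):
    img = rng.random(shape)
    f = encode(img, small_weights)
    assert f.shape == shape + (small_cfg.encoder_out_channels,)
    rec = decode(f, small_weights)
    assert rec.shape == shape


class TestMCBlock:
    def test_output_channels_match_config(self, small_cfg, small_weights, rng):
        out = mc_block(rng.random((12, 12)), small_cfg, small_weights)
        assert out.shape == (12, 12, small_cfg.encoder_out_channels)

    def test_zero_input_zero_biases_gives_zero(self, small_cfg, small_weights):
        out = mc_block(np.zeros((10, 10)), small_cfg, small_weights)
        assert np.all(out == 0)

    def test_dense_and_plain_variants_differ(self, rng):
        img = rng.random((12, 12))
        outs = {}
        for variant in ("res2b", "res2db"):
            cfg = dataclasses.replace(NetConfig.small(), dense_variant=variant)
            w = init_weights(cfg, seed=1)
            outs[variant] = mc_block(img, cfg, w)
        assert outs["res2b"].shape == outs["res2db"].shape
        assert not np.allclose(outs["res2b"], outs["res2db"])


class TestAttention:
    def test_channel_attention_constant_input_degeneracy(self, small_cfg, small_weights):
        """Spatially constant input: max-pool equals avg-pool, so both
        bottleneck paths coincide and the gate is sigmoid of twice one path."""
        const = np.ones((9, 9, small_cfg.encoder_out_channels)) * 0.3
        out = channel_attention(const, small_weights)
        ratio = out / const
        assert np.allclose(ratio, ratio[0, 0, :], atol=1e-6)

    def test_channel_gate_in_unit_interval_and_per_channel(
        self, small_cfg, small_weights, rng
    ):
        x = rng.normal(size=(8, 8, small_cfg.encoder_out_channels))
        out = channel_attention(x, small_weights)
        ratio = out[x != 0] / x[x != 0]
        assert np.all(ratio > 0) and np.all(ratio < 1)
        per_channel = out / np.where(x == 0, 1, x)
        for c in range(x.shape[2]):
            vals = per_channel[:, :, c][x[:, :, c] != 0]
            assert np.allclose(vals, vals.flat[0], atol=1e-5)

    def test_spatial_gate_shared_across_channels(self, small_weights, rng):
        x = rng.normal(size=(8, 8, 32))
        out = spatial_attention(x, small_weights)
        ratio = np.where(x != 0, out / np.where(x == 0, 1, x), np.nan)
        per_pixel = np.nanstd(ratio, axis=2)
        assert np.nanmax(per_pixel) < 1e-5
        flat = ratio[np.isfinite(ratio)]
        assert np.all(flat > 0) and np.all(flat < 1)

    def test_spatial_attention_single_channel_pools_equal_input(self, rng):
        """With one channel, channel max-pool and avg-pool are both the input."""
        from medfuse import _autodiff as ad

        x = Tensor(rng.normal(size=(1, 6, 6, 1)))
        assert np.array_equal(ad.channel_max_pool(x).data, x.data)
        assert np.array_equal(ad.channel_avg_pool(x).data, x.data)

    def test_ma_block_shape_and_determinism(self, small_cfg, small_weights, rng):
        x = rng.normal(size=(8, 8, small_cfg.encoder_out_channels))
        out1 = ma_block(x, small_weights)
        out2 = ma_block(x, small_weights)
        assert out1.shape == x.shape
        assert np.array_equal(out1, out2)

    def test_ma_block_zero_input_zero_biases_gives_zero(self, small_cfg, small_weights):
        out = ma_block(np.zeros((8, 8, small_cfg.encoder_out_channels)), small_weights)
        assert np.allclose(out, 0)


class TestEncoderDecoder:
    def test_siamese_contract_same_weights_object(self, small_weights, clean_pair):
        f_ct = encode(clean_pair.ct, small_weights)
        f_mri = encode(clean_pair.mri, small_weights)
        assert f_ct.shape == f_mri.shape  # one parameter set serves both

    def test_decoder_has_five_conv_layers(self, small_weights):
        names = [k for k in small_weights.params if k.startswith("dec") and
                 not k.endswith("_b")]
        assert sorted(names) == ["dec1", "dec2", "dec3", "dec4", "dec5"]

    def test_decoder_output_can_be_negative_preclip(self, small_weights, rng):
        f = rng.normal(size=(8, 8, 32)) * 5
        raw = decode(f, small_weights, clip=False)
        clipped = decode(f, small_weights, clip=True)
        assert raw.min() < 0
        assert clipped.min() >= 0 and clipped.max() <= 1

    def test_channel_mismatch_rejected(self, small_weights, rng):
        with pytest.raises(ValueError):
            decode(rng.normal(size=(8, 8, 17)), small_weights)

    def test_gradient_reaches_every_parameter(self, small_cfg):
        cfg = small_cfg
        weights = init_weights(cfg, seed=2)
        tensors = as_tensors(weights, trainable=True)
        x = Tensor(np.random.default_rng(0).random((1, 12, 12, 1), dtype=np.float32) )
        out = decode_forward(encode_forward(x, tensors, cfg), tensors, cfg)
        ((out - x) * (out - x)).mean().backward()
        missing = [k for k, t in tensors.items() if t.grad is None]
        assert missing == []
        nonzero = [k for k, t in tensors.items() if np.any(t.grad != 0)]
        assert len(nonzero) == len(tensors)


class TestCheckpointRoundTrip:
    def test_save_load_preserves_params_and_config(self, small_weights, tmp_path):
        path = tmp_path / "w.npz"
        save_weights(small_weights, path)
        back = load_weights(path)
        assert back.config == small_weights.config
        for k, v in small_weights.params.items():
            assert np.array_equal(back.params[k], v)

    def test_shape_validation_on_load(self, small_weights, tmp_path):
        import copy

        broken = copy.deepcopy(small_weights)
        broken.params["dec3"] = broken.params["dec3"][:, :, :2, :]
        path = tmp_path / "bad.npz"
        save_weights(broken, path)
        with pytest.raises(ValueError):
            load_weights(path)
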