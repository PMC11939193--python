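import numpy as np
import pytest
from scipy.special import erf, expit

from bcgnet.model import (BHNet, BHNetConfig, ConfigurationError, MSCAM,
                          count_parameters, load_model, ms_cam_fuse, save_model)
from bcgnet.nn import Adam, Conv1d
from bcgnet.nn import functional as F
from bcgnet.nn.autograd import backward
from conftest import tiny_config


def _gelu(x):
    return 0.5 * x * (1.0 + erf(x / np.sqrt(2.0)))


def mscam_oracle(module, x):
    """Step-by-step recomputation of the fusion equations outside the graph:
    omega = BN(conv2(GELU(conv1(GAP(X))))), L likewise per position,
    X' = X * sigmoid(omega + L)."""
    def conv1x1(layer, v):
        return (np.einsum("oc,ncl->nol", layer.weight.data[:, :, 0], v)
                + layer.bias.data[None, :, None])

    def bn_eval(bn, v):
        shape = (1, -1, 1)
        xhat = (v - bn.running_mean.reshape(shape)) / np.sqrt(
            bn.running_var.reshape(shape) + bn.eps)
        return bn.gamma.data.reshape(shape) * xhat + bn.beta.data.reshape(shape)

    gap = x.mean(axis=2, keepdims=True)
    omega = bn_eval(module.g_bn,
                    conv1x1(module.g_conv2, _gelu(conv1x1(module.g_conv1, gap))))
    local = bn_eval(module.l_bn,
                    conv1x1(module.l_conv2, _gelu(conv1x1(module.l_conv1, x))))
    att = expit(omega + local)
    return omega, local, att, x * att


def _randomized_mscam(channels=64, bottleneck=32, seed=0):
    rng = np.random.default_rng(seed)
    module = MSCAM(channels, bottleneck, rng, dtype=np.float64).eval()
    for bn in (module.g_bn, module.l_bn):
        bn.running_mean[:] = rng.normal(size=channels)
        bn.running_var[:] = rng.uniform(0.5, 2.0, size=channels)
        bn.gamma.data = rng.normal(1.0, 0.2, channels)
        bn.beta.data = rng.normal(0.0, 0.2, channels)
    return module, rng


class TestMSCAM:
    def test_matches_equation_oracle(self):
        module, rng = _randomized_mscam()
        x = rng.normal(size=(2, 64, 4))
        ctx = ms_cam_fuse(module, x)
        omega, local, att, refined = mscam_oracle(module, x)
        np.testing.assert_allclose(ctx.global_context, omega, atol=1e-5)
        np.testing.assert_allclose(ctx.local_context, local, atol=1e-5)
        np.testing.assert_allclose(ctx.attention, att, atol=1e-5)
        np.testing.assert_allclose(ctx.refined, refined, atol=1e-5)

    def test_zero_input_stays_zero_and_attention_bounded(self):
        module, _ = _randomized_mscam(seed=3)
        ctx = ms_cam_fuse(module, np.zeros((1, 64, 4)))
        np.testing.assert_array_equal(ctx.refined, 0.0)
        assert np.all(ctx.attention > 0.0) and np.all(ctx.attention < 1.0)

    def test_never_amplifies_magnitude(self):
        module, rng = _randomized_mscam(seed=4)
        x = rng.normal(size=(3, 64, 8))
        ctx = ms_cam_fuse(module, x)
        assert np.all(np.abs(ctx.refined) <= np.abs(x))
        nz = x != 0
        assert np.all(np.abs(ctx.refined[nz]) < np.abs(x[nz]))

    def test_channel_mismatch_is_shape_error(self):
        module, rng = _randomized_mscam()
        with pytest.raises(ValueError, match="channels"):
            ms_cam_fuse(module, rng.normal(size=(1, 32, 4)))


class TestArchitecture:
    def test_default_geometry(self):
        cfg = BHNetConfig()
        assert cfg.length_chain() == [250, 125, 63, 32, 16, 8, 4, 2]
        model = BHNet(cfg)
        x = np.random.default_rng(0).normal(size=(2, 1000)).astype(np.float32)
        model.eval()
        model.forward(x)
        # four taps at lengths 16, 8, 4, 2; adaptive pooling is the identity
        for t, (length, channels) in enumerate(
                zip((16, 8, 4, 2), (48, 48, 64, 64))):
            tap = model.activations[f"tap{t}_pooled"]
            assert tap.data.shape[1:] == (channels, length)
        assert model.activations["extra_block"].data.shape[1] == 64

    def test_parameter_count_near_one_megaparameter(self):
        count = count_parameters(BHNet(BHNetConfig()))
        assert abs(count - 1.02e6) / 1.02e6 < 0.20

    def test_toy_parameter_count_closed_form(self):
        cfg = tiny_config()
        model = BHNet(cfg)
        k, sk, c = cfg.block_kernel, cfg.stem_kernel, 4
        conv = c * c * k + c          # one block conv, same channels
        bn = 2 * c
        res_block = 2 * (bn + conv)   # two BN+conv repeats, no projection
        stem = (1 * c * sk + c) + bn + (c * c * sk + c)
        mscam = 2 * ((c * 2 + 2) + (2 * c + c) + bn)   # two branches
        head = (2 * c) * cfg.scale_lengths[0] * cfg.n_classes + cfg.n_classes
        expected = stem + 3 * res_block + 2 * mscam + head
        assert count_parameters(model) == expected

    def test_freezing_reduces_count_by_layer_size(self):
        model = BHNet(tiny_config())
        full = count_parameters(model)
        w = model.head.weight
        w.requires_grad = False
        assert count_parameters(model) == full - w.data.size

    def test_too_short_input_is_configuration_error(self):
        with pytest.raises(ConfigurationError):
            tiny_config(input_length=0)

    def test_scale_lengths_must_decrease(self):
        with pytest.raises(ConfigurationError):
            tiny_config(scale_lengths=(2, 4))


class TestForward:
    def test_rows_sum_to_one_and_finite(self):
        model = BHNet(tiny_config()).eval()
        x = np.random.default_rng(1).normal(size=(5, 64)).astype(np.float32)
        p = model.forward(x).data
        assert p.shape == (5, 2)
        assert np.all(np.isfinite(p))
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_duplicate_inputs_identical_rows_in_eval(self):
        model = BHNet(tiny_config()).eval()
        x = np.tile(np.random.default_rng(2).normal(size=(1, 64)), (3, 1))
        p = model.forward(x.astype(np.float32)).data
        np.testing.assert_array_equal(p[0], p[1])
        np.testing.assert_array_equal(p[0], p[2])

    def test_length_mismatch_raises(self):
        model = BHNet(tiny_config())
        with pytest.raises(ValueError, match="length"):
            model.forward(np.zeros((1, 65), dtype=np.float32))

    def test_gradient_reaches_nearly_all_parameters(self):
        model = BHNet(tiny_config())
        model.train()
        x = np.random.default_rng(3).normal(size=(8, 64)).astype(np.float32)
        y = np.array([0, 1] * 4)
        model.forward(x)
        loss = F.cross_entropy(model.activations["logits"], y)
        opt = Adam(model.parameters(), lr=1e-3)
        opt.zero_grad()
        backward(loss)
        params = model.parameters()
        live = [p for p in params if p.grad is not None and np.any(p.grad != 0)]
        assert len(live) >= 0.99 * len(params)

    def test_checkpoint_round_trip(self, tmp_path):
        model = BHNet(tiny_config(seed=5)).eval()
        x = np.random.default_rng(4).normal(size=(3, 64)).astype(np.float32)
        before = model.forward(x).data.copy()
        save_model(model, tmp_path / "ckpt")
        back = load_model(tmp_path / "ckpt").eval()
        np.testing.assert_array_equal(back.forward(x).data, before)


def test_single_conv_parameter_arithmetic():
    conv = Conv1d(16, 16, 17, np.random.default_rng(0))
    assert conv.weight.data.size + conv.bias.data.size == 16 * 16 * 17 + 16 == 4368
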