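"""Architecture contracts: DCC channels, global channel attention
(brute-force oracle), shape preservation, receptive fields, parameter
counts, trainability."""

import numpy as np
import pytest

from gobletseg.nn import (Tensor, ModelConfig, build_dcau_net,
                          build_unet_baseline)
from gobletseg.nn.dcau import (GCA, SemanticChannel, TextureChannel, gca,
                               semantic_channel, texture_channel)


# ---- global channel attention -------------------------------------------

def gca_bruteforce(fused: np.ndarray, w: np.ndarray, b: float) -> np.ndarray:
    """Scalar-loop evaluation of the attention algebra on one C x H x W map."""
    C, H, W = fused.shape
    i_s = np.zeros(C)
    for c in range(C):
        acc = 0.0
        for i in range(H):
            for j in range(W):
                acc += fused[c, i, j]
        i_s[c] = acc / (H * W)
    i_a = np.zeros((H, W))
    for i in range(H):
        for j in range(W):
            acc = b
            for c in range(C):
                acc += w[c] * fused[c, i, j]
            i_a[i, j] = acc
    sig = 1.0 / (1.0 + np.exp(-i_a))
    out = np.zeros_like(fused)
    for c in range(C):
        for i in range(H):
            for j in range(W):
                out[c, i, j] = sig[i, j] * i_s[c] * fused[c, i, j]
    return out


@pytest.mark.parametrize("shape", [(4, 6, 6), (8, 8, 8), (1, 3, 5)])
def test_gca_matches_scalar_loop_oracle(rng, shape):
    sem = rng.normal(size=shape)
    tex = rng.normal(size=shape)
    w = rng.normal(size=shape[0])
    b = float(rng.normal())
    out = gca(sem, tex, weights=w, bias=b)
    ref = gca_bruteforce(sem + tex, w, b)
    np.testing.assert_allclose(out.data[0], ref, atol=1e-6)


def test_gca_zero_weights_halves_channel_mean(rng):
    """With a zero 1x1 conv the gate is sigmoid(0)=0.5 everywhere, so the
    refinement map is exactly 0.5 * per-channel mean."""
    fused = rng.normal(size=(3, 4, 4))
    mod = GCA(3, rng=np.random.default_rng(0))
    mod.squeeze.w.data[...] = 0.0
    mod.squeeze.b.data[...] = 0.0
    mod.eval()
    out = mod(Tensor(fused[None]))
    i_s = fused.mean(axis=(1, 2))
    expected = 0.5 * i_s[:, None, None] * fused
    np.testing.assert_allclose(out.data[0], expected, atol=1e-12)


def test_gca_constant_input_descriptor_exact(rng):
    v = rng.normal(size=3)
    fused = np.broadcast_to(v[:, None, None], (3, 5, 5)).copy()
    np.testing.assert_allclose(fused.mean(axis=(1, 2)), v, atol=0)


def test_gca_attention_strictly_bounded(rng):
    mod = GCA(4, rng=np.random.default_rng(1))
    mod.eval()
    fused = Tensor(rng.normal(size=(1, 4, 6, 6)) * 10)
    gate = mod.squeeze(fused).sigmoid().data
    assert np.all(gate > 0) and np.all(gate < 1)
    assert np.isfinite(mod(fused).data).all()


# ---- DCC channels --------------------------------------------------------

def _support(out_grad_probe):
    """Receptive field of output center pixel via input-gradient support."""
    return np.nonzero(np.abs(out_grad_probe) > 1e-12)


def _input_gradient(module, n_in, size):
    x = Tensor(np.random.default_rng(0).normal(size=(1, n_in, size, size)),
               requires_grad=True)
    module.eval()
    y = module(x)
    g = np.zeros_like(y.data)
    g[0, :, size // 2, size // 2] = 1.0
    y.backward(g)
    return x.grad[0, 0]


def test_semantic_stacked_path_has_5x5_receptive_field():
    rng0 = np.random.default_rng(0)
    mod = SemanticChannel(1, 4, residual=False, rng=rng0)
    gsingle = _input_gradient(mod.single, 1, 11)
    gstacked = _input_gradient(mod.stacked, 1, 11)
    rs, cs = _support(gsingle)
    assert np.ptp(rs) + 1 == 3 and np.ptp(cs) + 1 == 3
    rs, cs = _support(gstacked)
    assert np.ptp(rs) + 1 == 5 and np.ptp(cs) + 1 == 5


def test_texture_channel_receptive_field_spans_kxk():
    mod = TextureChannel(1, 4, k=7, rng=np.random.default_rng(0))
    g = _input_gradient(mod, 1, 15)
    rs, cs = _support(g)
    assert np.ptp(rs) + 1 == 7 and np.ptp(cs) + 1 == 7


def test_channel_shapes_match_for_fusion(rng):
    x = rng.normal(size=(3, 12, 12))
    s = semantic_channel(x, cout=8)
    t = texture_channel(x, cout=8)
    assert s.shape == t.shape == (1, 8, 12, 12)


def test_asymmetric_pair_parameter_saving():
    """k x 1 + 1 x k factorization: 2k vs k^2 weights per channel pair."""
    cin = cout = 8
    for k in (3, 5, 7, 9):
        pair = 2 * k * cin * cout
        full = k * k * cin * cout
        assert pair < full


# ---- whole networks ------------------------------------------------------

@pytest.fixture(scope="module")
def tiny_cfg():
    return ModelConfig(depth=2, base_channels=4, seed=0)


def test_dcau_output_contract(tiny_cfg, rng):
    net = build_dcau_net(tiny_cfg).eval()
    y = net(Tensor(rng.random((1, 1, 32, 32))))
    assert y.shape == (1, 1, 32, 32)
    assert np.all(y.data >= 0) and np.all(y.data <= 1)


def test_both_models_accept_identical_batches(tiny_cfg, rng):
    batch = Tensor(rng.random((2, 1, 32, 32)))
    for build in (build_dcau_net, build_unet_baseline):
        y = build(tiny_cfg).eval()(batch)
        assert y.shape == (2, 1, 32, 32)


def test_indivisible_input_raises(tiny_cfg, rng):
    net = build_dcau_net(tiny_cfg)
    with pytest.raises(ValueError, match="divisible"):
        net(Tensor(rng.random((1, 1, 30, 30))))


def test_encoder_halves_spatial_dims_per_stage(rng):
    cfg = ModelConfig(depth=3, base_channels=2, seed=0)
    net = build_dcau_net(cfg).eval()
    x = Tensor(rng.random((1, 1, 64, 64)))
    sizes = []
    for stage in net.enc_stages:
        fused, _ = stage(x)
        x = net.pool(fused)
        sizes.append(x.shape[-1])
    assert sizes == [32, 16, 8]


def test_zero_input_zero_bias_gives_zero_features():
    mod = SemanticChannel(2, 3, residual=False, rng=np.random.default_rng(0))
    mod.eval()  # BN identity statistics: running mean 0, var 1
    y = mod(Tensor(np.zeros((1, 2, 8, 8))))
    np.testing.assert_allclose(y.data, 0.0, atol=1e-12)


def test_unet_classic_parameter_count():
    """Classic widths 64..1024 with 2x2 up-convolutions: about 31M."""
    expected = 0
    widths = [64, 128, 256, 512]
    cin = 1
    for w in widths:                      # encoder double convs
        expected += cin * w * 9 + w + w * w * 9 + w
        cin = w
    expected += cin * 1024 * 9 + 1024 + 1024 * 1024 * 9 + 1024  # bottleneck
    cin = 1024
    for w in reversed(widths):            # up-conv + double conv
        expected += cin * w * 4 + w
        expected += 2 * w * w * 9 + w + w * w * 9 + w
        cin = w
    expected += 64 * 1 + 1                # 1x1 head
    net = build_unet_baseline(ModelConfig())
    assert net.n_parameters() == expected
    assert 30e6 < expected < 32e6


def test_forward_backward_finite_on_synthetic_tile(tiny_cfg, small_scene):
    from gobletseg.losses import combined_loss
    net = build_dcau_net(tiny_cfg)
    img = small_scene.image.pixels[:64, :64] / 65535.0
    msk = small_scene.mask[:64, :64].astype(float)
    prob = net(Tensor(img[None, None]))
    loss = combined_loss(prob, msk[None, None])
    assert np.isfinite(loss.data)
    loss.backward()
    for p in net.parameters():
        assert p.grad is not None and np.isfinite(p.grad).all()
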