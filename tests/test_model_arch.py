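"""Architecture contracts: channel splits, EGMA/ADown equation oracles,
shape arithmetic and parameter accounting."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.special import expit

from splashquant.model import (ADown, AdownConfig, EGMA, EgmaConfig,
                               ModelConfig, adown_channel_split, build_model,
                               count_parameters)
from splashquant.nn.autograd import Tensor


# ---------------------------------------------------------------------------
# channel split
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("c2,expect", [
    (64, (21, 21, 22)), (3, (1, 1, 1)), (256, (85, 85, 86)),
])
def test_adown_split_examples(c2, expect):
    assert adown_channel_split(c2) == expect


def test_adown_split_conservation_exhaustive():
    for c2 in range(3, 1025):
        ca, cb, cc = adown_channel_split(c2)
        assert ca == cb == c2 // 3
        assert ca + cb + cc == c2
        assert min(ca, cb, cc) >= 1


def test_adown_split_rejects_tiny():
    with pytest.raises(ValueError):
        adown_channel_split(2)


# ---------------------------------------------------------------------------
# EGMA: straight-line recomputation oracle
# ---------------------------------------------------------------------------

def _naive_conv3x3(x, w):
    """Direct (loop) 3x3 same-padding convolution, (B,C,H,W)->(B,1,H,W)."""
    b, c, h, wd = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    out = np.zeros((b, 1, h, wd))
    for i in range(h):
        for j in range(wd):
            out[:, 0, i, j] = np.einsum(
                "bckl,ckl->b", xp[:, :, i:i + 3, j:j + 3], w[0])
    return out


def _egma_oracle(x, mod):
    """Recompute E, Xe, G, Ac, Y directly from the module weights."""
    bn = mod.edge_bn
    e = _naive_conv3x3(x, mod.edge_w.data)
    e = (e - bn.running_mean[0]) / np.sqrt(bn.running_var[0] + bn.eps)
    e = expit(bn.gamma.data[0] * e + bn.beta.data[0])
    xe = x * e
    g = xe.mean(axis=(2, 3), keepdims=True)
    h = np.maximum(np.einsum("oc,bcij->boij", mod.mlp_w1.data[:, :, 0, 0], g), 0)
    ac = expit(np.einsum("oc,bcij->boij", mod.mlp_w2.data[:, :, 0, 0], h))
    return e, xe, g, ac, x * ac * (1 + e)


@pytest.mark.parametrize("seed", range(8))
def test_egma_forward_matches_equation_oracle(seed):
    rng = np.random.default_rng(seed)
    mod = EGMA(rng, EgmaConfig(channels=16, mlp_reduction=4)).eval()
    # non-trivial BN statistics so the oracle exercises normalization
    mod.edge_bn.running_mean[:] = rng.normal(0, 0.5)
    mod.edge_bn.running_var[:] = rng.uniform(0.5, 2.0)
    x = rng.normal(size=(2, 16, 6, 7)).astype(np.float32)
    inter = mod.forward_detailed(Tensor(x))
    e, xe, g, ac, y = _egma_oracle(x.astype(np.float64), mod)
    np.testing.assert_allclose(inter.edge_map, e, atol=1e-5)
    np.testing.assert_allclose(inter.weighted, xe, atol=1e-5)
    np.testing.assert_allclose(inter.pooled, g, atol=1e-5)
    np.testing.assert_allclose(inter.channel_weights, ac, atol=1e-5)
    np.testing.assert_allclose(inter.output, y, atol=1e-5)


def test_egma_zero_propagation_and_ranges(rng):
    mod = EGMA(rng, EgmaConfig(channels=32)).eval()
    z = mod.forward_detailed(Tensor(np.zeros((2, 32, 8, 8), np.float32)))
    assert np.all(z.output == 0)
    x = rng.normal(size=(2, 32, 8, 8)).astype(np.float32)
    inter = mod.forward_detailed(Tensor(x))
    assert np.all((inter.edge_map > 0) & (inter.edge_map < 1))
    assert np.all((inter.channel_weights > 0) & (inter.channel_weights < 1))
    assert np.all(np.abs(inter.output) <= 2 * np.abs(x) + 1e-6)
    assert inter.output.shape == x.shape


def test_egma_rejects_bad_config_and_channels(rng):
    with pytest.raises(ValueError):
        EgmaConfig(channels=30, mlp_reduction=4)
    mod = EGMA(rng, EgmaConfig(channels=16))
    with pytest.raises(ValueError):
        mod(Tensor(np.zeros((1, 8, 4, 4), np.float32)))


# ---------------------------------------------------------------------------
# ADown: straight-line recomputation oracle
# ---------------------------------------------------------------------------

def _silu(x):
    return x * expit(x)


def _bn_eval(x, bn):
    inv = 1 / np.sqrt(bn.running_var + bn.eps)
    return (bn.gamma.data * (x.transpose(0, 2, 3, 1) - bn.running_mean) * inv
            + bn.beta.data).transpose(0, 3, 1, 2)


def _adown_oracle(x, mod):
    b, c, h, w = x.shape
    avg = x.reshape(b, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))
    mx = x.reshape(b, c, h // 2, 2, w // 2, 2).max(axis=(3, 5))
    y1 = np.einsum("oc,bchw->bohw", mod.wa.data[:, :, 0, 0], avg)
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    ho, wo = h // 2, w // 2
    y2 = np.zeros((b, mod.wb.data.shape[0], ho, wo))
    for i in range(ho):
        for j in range(wo):
            patch = xp[:, :, 2 * i:2 * i + 3, 2 * j:2 * j + 3]
            y2[:, :, i, j] = np.einsum("bckl,ockl->bo", patch, mod.wb.data)
    y3 = np.einsum("oc,bchw->bohw", mod.wc.data[:, :, 0, 0], mx)
    parts = [_silu(_bn_eval(y, bn)) for y, bn in
             ((y1, mod.bna), (y2, mod.bnb), (y3, mod.bnc))]
    return np.concatenate(parts, axis=1)


@pytest.mark.parametrize("seed", range(8))
def test_adown_forward_matches_equation_oracle(seed):
    rng = np.random.default_rng(seed)
    mod = ADown(rng, AdownConfig(8, 9)).eval()
    for bn in (mod.bna, mod.bnb, mod.bnc):
        bn.running_mean[:] = rng.normal(0, 0.3, bn.running_mean.shape)
        bn.running_var[:] = rng.uniform(0.5, 2.0, bn.running_var.shape)
    x = rng.normal(size=(2, 8, 10, 6)).astype(np.float32)
    out = mod(Tensor(x)).data
    ref = _adown_oracle(x.astype(np.float64), mod)
    assert out.shape == (2, 9, 5, 3)
    np.testing.assert_allclose(out, ref, atol=1e-5)


def test_adown_branch_order_is_part_of_contract(rng):
    """Swapping branch weights changes the output -> concat order matters;
    reloading saved weights reproduces the forward bit-for-bit."""
    cfg = AdownConfig(6, 6)
    mod = ADown(rng, cfg).eval()
    x = Tensor(rng.normal(size=(1, 6, 8, 8)).astype(np.float32))
    base = mod(x).data
    # permute: give the avg branch the max branch's weights and vice versa
    mod2 = ADown(np.random.default_rng(0), cfg).eval()
    mod2.load_state_dict(mod.state_dict())
    mod2.wa.data, mod2.wc.data = mod2.wc.data.copy(), mod2.wa.data.copy()
    assert not np.allclose(mod2(x).data, base)
    # round-trip determinism
    mod3 = ADown(np.random.default_rng(99), cfg).eval()
    mod3.load_state_dict(mod.state_dict())
    assert np.array_equal(mod3(x).data, base)


def test_adown_rejects_odd_spatial(rng):
    mod = ADown(rng, AdownConfig(4, 6))
    with pytest.raises(ValueError):
        mod(Tensor(np.zeros((1, 4, 7, 8), np.float32)))


# ---------------------------------------------------------------------------
# builder: shapes and parameter accounting
# ---------------------------------------------------------------------------

def test_forward_shape_contract(tiny_net):
    out = tiny_net.forward(np.zeros((1, 3, 64, 64), np.float32))
    assert {k: v.shape[2:] for k, v in out.items()} == {
        "P3": (8, 8), "P4": (4, 4), "P5": (2, 2)}


def test_forward_shape_contract_with_p2():
    cfg = ModelConfig(input_size=(128, 128), scales=("P2", "P3", "P4", "P5"),
                      width_multiple=0.25, seed=1)
    net = build_model(cfg).eval()
    out = net.forward(np.zeros((1, 3, 128, 128), np.float32))
    assert [v.shape[2:] for v in out.values()] == [
        (32, 32), (16, 16), (8, 8), (4, 4)]


def test_config_validation():
    with pytest.raises(ValueError):
        ModelConfig(input_size=(100, 100))
    with pytest.raises(ValueError):
        ModelConfig(scales=("P2", "P3", "P4", "P5"), input_size=(96, 96))
    with pytest.raises(ValueError):
        ModelConfig(egma_layers=(3,))
    with pytest.raises(ValueError):
        ModelConfig(scales=("P4", "P5"))


def test_param_report_totals_consistent(tiny_net):
    rep = count_parameters(tiny_net)
    assert rep.total == sum(rep.blocks.values())
    assert rep.trainable == rep.total - tiny_net.cfg.reg_max  # fixed DFL vector
    assert all(v >= 0 for v in rep.blocks.values())


def test_module_deltas_are_additive_small_scale():
    """EGMA and ADown parameter deltas are independent of each other."""
    def total(**kw):
        cfg = ModelConfig(input_size=(64, 64), width_multiple=0.25, **kw)
        return count_parameters(build_model(cfg)).total

    n1 = total()
    n3 = total(egma_layers=(2, 4, 6, 8))
    n4 = total(use_adown=True)
    n7 = total(egma_layers=(2, 4, 6, 8), use_adown=True)
    assert n7 == n1 + (n3 - n1) + (n4 - n1)
    assert n3 > n1 and n4 < n1


def test_egma_parameter_delta_closed_form():
    """One EGMA unit costs 9C + 2 + C^2/2 parameters (edge conv + BN(1) +
    bias-free bottlenecked MLP at reduction 4)."""
    base = count_parameters(build_model(
        ModelConfig(input_size=(64, 64)))).total
    with_egma = count_parameters(build_model(
        ModelConfig(input_size=(64, 64), egma_layers=(2,)))).total
    c = 128  # stage-2 output channels at YOLO11s width
    assert with_egma - base == 9 * c + 2 + c * c // 2


@given(st.integers(3, 2048))
def test_adown_split_property(c2):
    ca, cb, cc = adown_channel_split(c2)
    assert ca + cb + cc == c2 and cc - ca in (0, 1, 2)
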