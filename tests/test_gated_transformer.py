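"""Gated transformer layer and token-space U branch."""

import numpy as np
import pytest

from vesseltext.autodiff import Tensor
from vesseltext.gated_transformer import (GateParams, GatedTransformerLayer,
                                          VitBranch, gate_param_count, gate_signal,
                                          gated_layer)


# ------------------------------------------------------------- gate_signal
def test_gate_zero_weights_half():
    g = GateParams.zeros(8)
    vals = gate_signal(np.random.default_rng(0).standard_normal((5, 8)), g, "attn")
    np.testing.assert_array_equal(vals, np.full((5, 1), 0.5))


def test_gate_negative_bias_saturates():
    g = GateParams.zeros(8)
    g.attn_bias = np.array([-20.0])
    vals = gate_signal(np.zeros((3, 8)), g, "attn")
    assert (vals < 1e-8).all()


def test_gate_matches_affine_sigmoid_oracle(rng):
    d, gdim = 8, 8
    g = GateParams(rng.standard_normal((d, gdim)), rng.standard_normal(gdim),
                   rng.standard_normal((d, gdim)), rng.standard_normal(gdim))
    x = rng.standard_normal((6, d))
    for which, w, b in (("attn", g.attn_weight, g.attn_bias),
                        ("mlp", g.mlp_weight, g.mlp_bias)):
        oracle = 1.0 / (1.0 + np.exp(-(x @ w + b)))
        np.testing.assert_allclose(gate_signal(x, g, which), oracle, atol=1e-9)


def test_gate_errors(rng):
    g = GateParams.zeros(8)
    with pytest.raises(ValueError):
        gate_signal(rng.standard_normal((3, 5)), g, "attn")
    with pytest.raises(ValueError):
        gate_signal(rng.standard_normal((3, 8)), g, "bogus")
    with pytest.raises(ValueError):
        GateParams(np.zeros((8, 3)), np.zeros(3), np.zeros((8, 3)), np.zeros(3))


def test_gate_values_open_interval(rng):
    layer = GatedTransformerLayer(8, 2, rng)
    layer.gate_attn_w.data = rng.standard_normal((8, 1))
    x = rng.standard_normal((4, 8)) * 2
    g = GateParams(layer.gate_attn_w.data, layer.gate_attn_b.data,
                   layer.gate_mlp_w.data, layer.gate_mlp_b.data)
    vals = gate_signal(x, g, "attn")
    assert (vals > 0).all() and (vals < 1).all()


# ------------------------------------------------------------- gated_layer
def _ungated_forward(layer, x):
    """Same weights, plain residuals (the gate->1 reference)."""
    t = Tensor(x[None])
    y1 = layer.attn(layer.norm1(t)) + t
    y = layer.mlp(layer.norm2(y1)) + y1
    return y.data[0]


def test_gate_zero_limit_identity(rng):
    layer = GatedTransformerLayer(8, 2, rng)
    layer.gate_attn_b.data = np.array([-1e4])
    layer.gate_mlp_b.data = np.array([-1e4])
    x = rng.standard_normal((5, 8))
    np.testing.assert_array_equal(gated_layer(x, layer), x)


def test_gate_one_limit_equals_ungated(rng):
    layer = GatedTransformerLayer(8, 2, rng)
    layer.gate_attn_b.data = np.array([1e4])
    layer.gate_mlp_b.data = np.array([1e4])
    x = rng.standard_normal((5, 8))
    np.testing.assert_allclose(gated_layer(x, layer), _ungated_forward(layer, x), atol=1e-12)


def test_gate_half_compositional_oracle(rng):
    """At init (gates exactly 0.5) the layer equals 0.5*Attn + x then 0.5*MLP + y'
    computed from the separately exercised sub-blocks."""
    layer = GatedTransformerLayer(8, 2, rng)  # zero gate params => gates 0.5
    x = rng.standard_normal((3, 8))
    t = Tensor(x[None])
    y1 = layer.attn(layer.norm1(t)) * 0.5 + t
    y = layer.mlp(layer.norm2(y1)) * 0.5 + y1
    np.testing.assert_allclose(gated_layer(x, layer), y.data[0], atol=1e-9)


def test_gated_layer_matches_manual_gate_composition():
    rng = np.random.default_rng(7)
    for _ in range(100):
        d = int(rng.choice([4, 8]))
        n = int(rng.integers(2, 6))
        layer = GatedTransformerLayer(d, 2, rng)
        layer.gate_attn_w.data = 0.3 * rng.standard_normal((d, 1))
        layer.gate_attn_b.data = 0.3 * rng.standard_normal(1)
        layer.gate_mlp_w.data = 0.3 * rng.standard_normal((d, 1))
        layer.gate_mlp_b.data = 0.3 * rng.standard_normal(1)
        x = rng.standard_normal((n, d))
        g = GateParams(layer.gate_attn_w.data, layer.gate_attn_b.data,
                       layer.gate_mlp_w.data, layer.gate_mlp_b.data)
        t = Tensor(x[None])
        a = layer.attn(layer.norm1(t)).data[0]
        y1 = gate_signal(x, g, "attn") * a + x
        m = layer.mlp(layer.norm2(Tensor(y1[None]))).data[0]
        y = gate_signal(y1, g, "mlp") * m + y1
        np.testing.assert_allclose(gated_layer(x, layer), y, atol=1e-6)


def test_token_count_and_shape_preserved(rng):
    layer = GatedTransformerLayer(16, 4, rng)
    x = rng.standard_normal((9, 16))
    assert gated_layer(x, layer).shape == (9, 16)


def test_attention_rows_are_distributions(rng):
    layer = GatedTransformerLayer(8, 2, rng)
    gated_layer(rng.standard_normal((6, 8)), layer)
    attn = layer.attn.last_attention
    assert (attn >= 0).all()
    np.testing.assert_allclose(attn.sum(axis=-1), np.ones(attn.shape[:-1]), atol=1e-12)


def test_heads_must_divide_dim(rng):
    with pytest.raises(ValueError):
        GatedTransformerLayer(10, 3, rng)


def test_gate_param_count():
    assert gate_param_count(32, 1) == 2 * 33
    assert gate_param_count(32, 32) == 2 * (32 * 32 + 32)


# --------------------------------------------------------------- VitBranch
def _branch(rng, gated=True):
    return VitBranch(enc_channels=[4, 8], grid_edges=[8, 4], dim=16, heads=2,
                     rng=rng, text_dim=32, gated=gated)


def _feats(rng):
    return [Tensor(rng.standard_normal((1, 4, 32, 32))),
            Tensor(rng.standard_normal((1, 8, 16, 16)))]


def test_vit_zero_text_equals_no_text(rng):
    branch = _branch(rng)
    feats = _feats(rng)
    with_zero = branch(feats, Tensor(np.zeros((1, 1, 32))))
    without = branch(feats, None)
    for a, b in zip(with_zero, without):
        np.testing.assert_array_equal(a.data, b.data)


def test_vit_gate_zero_collapses_to_entry_tokens(rng):
    """With every gate saturated at 0 each layer is the identity, so depth-1
    outputs equal the projected entry tokens."""
    branch = VitBranch(enc_channels=[4], grid_edges=[8], dim=16, heads=2,
                       rng=rng, text_dim=32, gated=True)
    for layers in list(branch.down_layers) + list(branch.up_layers):
        for layer in layers:
            layer.gate_attn_b.data = np.array([-1e4])
            layer.gate_mlp_b.data = np.array([-1e4])
    feats = [Tensor(rng.standard_normal((1, 4, 32, 32)))]
    out = branch(feats, None)
    from vesseltext.autodiff import functional as F
    entry = F.avg_pool2d(branch.proj[0](feats[0]), 4)
    np.testing.assert_array_equal(out[0].data, entry.data)


def test_vit_multiscale_output_shapes(rng):
    branch = _branch(rng)
    out = branch(_feats(rng), Tensor(rng.standard_normal((1, 1, 32))))
    assert [o.shape for o in out] == [(1, 16, 8, 8), (1, 16, 4, 4)]


def test_vit_deterministic_across_runs():
    r1, r2 = np.random.default_rng(42), np.random.default_rng(42)
    b1, b2 = _branch(r1), _branch(r2)
    rng = np.random.default_rng(5)
    feats_data = [rng.standard_normal((1, 4, 32, 32)), rng.standard_normal((1, 8, 16, 16))]
    text = rng.standard_normal((1, 1, 32))
    o1 = b1([Tensor(f) for f in feats_data], Tensor(text))
    o2 = b2([Tensor(f) for f in feats_data], Tensor(text))
    for a, b in zip(o1, o2):
        np.testing.assert_array_equal(a.data, b.data)


def test_vit_text_dim_mismatch(rng):
    branch = _branch(rng)
    with pytest.raises(ValueError):
        branch(_feats(rng), Tensor(np.zeros((1, 1, 17))))
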