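"""SE block: spec examples, loop oracles and invariants."""

import numpy as np
import pytest

from vesseltext.autodiff import Tensor
from vesseltext.se_attention import (SEBlock, SEParams, bottleneck_dim, excite,
                                     recalibrate, se_block, se_param_count, squeeze)


# ------------------------------------------------------------ loop oracles
def squeeze_oracle(u):
    c, h, w = u.shape
    z = np.zeros(c)
    for ci in range(c):
        total = 0.0
        for i in range(h):
            for j in range(w):
                total += u[ci, i, j]
        z[ci] = total / (h * w)
    return z


def excite_oracle(z, p):
    hidden = np.zeros(p.w1.shape[0])
    for i in range(p.w1.shape[0]):
        acc = sum(p.w1[i, j] * z[j] for j in range(len(z)))
        hidden[i] = max(acc, 0.0)
    s = np.zeros(len(z))
    for i in range(len(z)):
        acc = sum(p.w2[i, j] * hidden[j] for j in range(len(hidden)))
        s[i] = 1.0 / (1.0 + np.exp(-acc))
    return s


def se_block_oracle(u, p):
    s = excite_oracle(squeeze_oracle(u), p)
    out = np.zeros_like(u)
    for ci in range(u.shape[0]):
        out[ci] = s[ci] * u[ci]
    return out


# ---------------------------------------------------------------- squeeze
def test_squeeze_constant_map():
    u = np.full((3, 4, 5), 3.0)
    np.testing.assert_array_equal(squeeze(u), [3.0, 3.0, 3.0])


def test_squeeze_single_channel():
    np.testing.assert_array_equal(squeeze(np.array([[[1.0, 2.0], [3.0, 4.0]]])), [2.5])


def test_squeeze_matches_loop_oracle(rng):
    u = rng.standard_normal((3, 4, 5))
    np.testing.assert_allclose(squeeze(u), squeeze_oracle(u), atol=1e-9)


def test_squeeze_rejects_empty():
    with pytest.raises(ValueError):
        squeeze(np.zeros((2, 0, 3)))
    with pytest.raises(ValueError):
        squeeze(np.zeros((2, 3)))


# ----------------------------------------------------------------- excite
def test_excite_zero_weights_gives_half():
    p = SEParams(np.zeros((2, 4)), np.zeros((4, 2)))
    np.testing.assert_array_equal(excite(np.array([1.0, -2.0, 3.0, 0.5]), p), [0.5] * 4)


def test_excite_saturation():
    p = SEParams(np.full((2, 4), 10.0), np.full((4, 2), 10.0))
    s = excite(np.ones(4), p)
    assert (s > 0.999).all()


def test_excite_matches_oracle(rng):
    p = SEParams.init(8, reduction=2, rng=rng)
    z = rng.standard_normal(8)
    np.testing.assert_allclose(excite(z, p), excite_oracle(z, p), atol=1e-9)


def test_excite_dim_mismatch():
    p = SEParams.init(8, reduction=2, rng=np.random.default_rng(0))
    with pytest.raises(ValueError):
        excite(np.zeros(5), p)


# ------------------------------------------------------------ recalibrate
def test_recalibrate_identity_and_annihilation(rng):
    u = rng.standard_normal((3, 4, 4))
    np.testing.assert_array_equal(recalibrate(u, np.ones(3)), u)
    np.testing.assert_array_equal(recalibrate(u, np.zeros(3)), np.zeros_like(u))


def test_recalibrate_scalar_half(rng):
    u = rng.standard_normal((1, 5, 5))
    np.testing.assert_allclose(recalibrate(u, np.array([0.5])), 0.5 * u)


def test_recalibrate_length_mismatch(rng):
    with pytest.raises(ValueError):
        recalibrate(rng.standard_normal((3, 2, 2)), np.ones(4))


# --------------------------------------------------------------- se_block
def test_se_block_zero_weights_halves_input(rng):
    u = rng.standard_normal((4, 3, 3))
    p = SEParams(np.zeros((1, 4)), np.zeros((4, 1)))
    np.testing.assert_allclose(se_block(u, p), 0.5 * u)


def test_se_block_constant_per_channel(rng):
    z = np.array([1.0, -0.5, 2.0])
    u = np.broadcast_to(z[:, None, None], (3, 4, 4)).copy()
    p = SEParams.init(3, reduction=1, rng=rng)
    s = excite_oracle(squeeze_oracle(u), p)
    np.testing.assert_allclose(se_block(u, p), (z * s)[:, None, None] * np.ones((3, 4, 4)))


def test_se_block_shape_preserved(rng):
    u = rng.standard_normal((16, 32, 32))
    p = SEParams.init(16, rng=rng)
    assert se_block(u, p).shape == (16, 32, 32)


def test_se_block_oracle_equivalence_many():
    rng = np.random.default_rng(99)
    for _ in range(100):
        c = int(rng.integers(1, 9))
        h, w = int(rng.integers(1, 9)), int(rng.integers(1, 9))
        u = rng.standard_normal((c, h, w))
        p = SEParams.init(c, reduction=int(rng.choice([1, 2, 4, 16])), rng=rng)
        np.testing.assert_allclose(se_block(u, p), se_block_oracle(u, p), atol=1e-6)


def test_se_block_boundedness(rng):
    u = rng.standard_normal((5, 6, 6))
    p = SEParams.init(5, reduction=2, rng=rng)
    out = se_block(u, p)
    assert (np.abs(out) <= np.abs(u) + 1e-12).all()


def test_se_block_channel_permutation_equivariance(rng):
    c = 6
    u = rng.standard_normal((c, 4, 4))
    p = SEParams.init(c, reduction=2, rng=rng)
    perm = rng.permutation(c)
    p_perm = SEParams(p.w1[:, perm], p.w2[perm, :])
    np.testing.assert_allclose(se_block(u[perm], p_perm), se_block(u, p)[perm], atol=1e-12)


# -------------------------------------------------------- module surface
def test_se_module_matches_functional(rng):
    block = SEBlock(6, rng, reduction=2)
    u = rng.standard_normal((6, 5, 5))
    p = SEParams(block.w1.data, block.w2.data)
    out = block(Tensor(u[None]))
    np.testing.assert_allclose(out.data[0], se_block(u, p), atol=1e-12)


def test_se_module_gradient_flows(rng):
    block = SEBlock(4, rng, reduction=2)
    # nonzero weights so the relu path is active
    block.w1.data = rng.uniform(0.1, 0.5, block.w1.data.shape)
    block.w2.data = rng.uniform(0.1, 0.5, block.w2.data.shape)
    u = Tensor(np.abs(rng.standard_normal((1, 4, 3, 3))) + 0.1)
    (block(u) ** 2).sum().backward()
    assert block.w1.grad is not None and np.abs(block.w1.grad).sum() > 0
    assert block.w2.grad is not None and np.abs(block.w2.grad).sum() > 0


def test_param_helpers():
    assert bottleneck_dim(32, 16) == 2
    assert bottleneck_dim(8, 16) == 1  # clamped
    assert se_param_count(32, 16) == 2 * 32 * 2
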