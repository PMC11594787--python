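"""Residual blocks: permutation, neutrality, shape and oracle equivalence."""

import numpy as np
import pytest

from conftest import set_all_weights_zero
from lmnet.attention import AttentionConfig
from lmnet.blocks import (BasicBlock, BlockConfig, CBAMDBlock, InceptionUnit,
                          ImprovedResNetBlock, SMBlock, channel_shuffle)
from lmnet.nn import Tensor
from oracles import (cbamd_block_oracle, improved_block_oracle,
                     inception_oracle, shuffle_naive, sm_block_oracle)

BLOCKS = [CBAMDBlock, ImprovedResNetBlock, SMBlock, BasicBlock]


def _tiny_cfg(in_ch=4, out_ch=4, stride=1, kind="CA", g=2, t=2.0):
    return BlockConfig(in_channels=in_ch, out_channels=out_ch, stride=stride,
                       branch_hidden=4, branch_reduce=2, groups_g=g,
                       expansion_t=t,
                       attention=AttentionConfig(kind=kind, reduction_r=2))


# -- channel shuffle ---------------------------------------------------

def test_channel_shuffle_permutation():
    x = np.arange(4, dtype=np.float32).reshape(1, 4, 1, 1)
    assert channel_shuffle(Tensor(x), 1).data.ravel().tolist() == [0, 1, 2, 3]
    assert channel_shuffle(Tensor(x), 2).data.ravel().tolist() == [0, 2, 1, 3]
    with pytest.raises(ValueError):
        channel_shuffle(Tensor(np.zeros((1, 6, 1, 1), np.float32)), 4)


def test_channel_shuffle_inverse_and_conservation(rng):
    x = rng.normal(size=(2, 6, 3, 3)).astype(np.float32)
    once = channel_shuffle(Tensor(x), 2)
    twice = channel_shuffle(once, 3)
    np.testing.assert_array_equal(twice.data, x)          # g then C/g inverts
    np.testing.assert_allclose(once.data.sum(axis=1), x.sum(axis=1), rtol=1e-6)
    # multiset of channel slices is conserved
    h_in = sorted(map(tuple, x.reshape(2, 6, -1)[0]))
    h_out = sorted(map(tuple, once.data.reshape(2, 6, -1)[0]))
    assert h_in == h_out
    np.testing.assert_array_equal(channel_shuffle(Tensor(x), 2).data,
                                  shuffle_naive(x, 2))


# -- generic block properties -----------------------------------------

@pytest.mark.parametrize("block_cls", BLOCKS)
def test_residual_neutrality(rng, block_cls):
    """Zero main-path weights (BN identity, eval) -> output == ReLU(x)."""
    block = block_cls(_tiny_cfg(8, 8), rng=rng)
    block.eval()
    set_all_weights_zero(block)
    for _, m in block.named_modules():           # restore BN identity scale
        if hasattr(m, "running_mean"):
            m.weight.data[...] = 1.0
    # zero convs kill the main path regardless of gates; identity path is Id
    x = rng.normal(size=(2, 8, 5, 5)).astype(np.float32)
    out = block(Tensor(x)).data
    np.testing.assert_allclose(out, np.maximum(x, 0), rtol=1e-6, atol=1e-7)


@pytest.mark.parametrize("block_cls", BLOCKS)
@pytest.mark.parametrize("in_ch,out_ch,stride,hw", [
    (64, 128, 2, 16), (32, 32, 1, 8),
])
def test_shape_contract(rng, block_cls, in_ch, out_ch, stride, hw):
    cfg = _tiny_cfg(in_ch, out_ch, stride, g=2, t=1.0)
    cfg = cfg.with_(branch_hidden=in_ch // 2, branch_reduce=in_ch // 4)
    block = block_cls(cfg, rng=rng)
    block.eval()
    x = rng.normal(size=(1, in_ch, hw, hw)).astype(np.float32)
    out = block(Tensor(x))
    assert out.shape == (1, out_ch, hw // stride, hw // stride)


@pytest.mark.parametrize("block_cls", BLOCKS)
def test_forward_is_deterministic(rng, block_cls):
    block = block_cls(_tiny_cfg(4, 4), rng=rng)
    block.eval()
    x = rng.normal(size=(1, 4, 6, 6)).astype(np.float32)
    a = block(Tensor(x)).data
    b = block(Tensor(x)).data
    np.testing.assert_array_equal(a, b)


def test_channel_mismatch_raises(rng):
    block = SMBlock(_tiny_cfg(4, 4), rng=rng)
    with pytest.raises(ValueError):
        block(Tensor(np.zeros((1, 8, 4, 4), np.float32)))
    with pytest.raises(ValueError):
        SMBlock(_tiny_cfg(4, 4, g=3), rng=rng)          # divisibility
    with pytest.raises(ValueError):
        InceptionUnit(BlockConfig(in_channels=6, out_channels=6), rng=rng)


# -- inception unit ----------------------------------------------------

def test_inception_conserves_channels_and_zeroes(rng):
    cfg = _tiny_cfg(8, 8)
    unit = InceptionUnit(cfg, rng=rng)
    x = rng.normal(size=(1, 8, 5, 5)).astype(np.float32)
    assert unit(Tensor(x)).shape == (1, 8, 5, 5)
    set_all_weights_zero(unit)
    np.testing.assert_array_equal(unit(Tensor(x)).data, 0.0)


def test_inception_matches_per_branch_oracle(rng):
    cfg = _tiny_cfg(4, 4)
    unit = InceptionUnit(cfg, rng=rng)
    x = rng.normal(size=(1, 4, 5, 5)).astype(np.float32)
    ref = inception_oracle(x.astype(np.float64), unit)
    np.testing.assert_allclose(unit(Tensor(x)).data, ref, rtol=1e-4, atol=1e-5)


def test_dilated_conv_preserves_spatial_size(rng):
    for d in (1, 2, 3):
        cfg = _tiny_cfg(4, 4).with_(dilation=d)
        block = ImprovedResNetBlock(cfg, rng=rng)
        block.eval()
        x = rng.normal(size=(1, 4, 9, 9)).astype(np.float32)
        assert block(Tensor(x)).shape == (1, 4, 9, 9)


# -- line-by-line oracle equivalence ----------------------------------

@pytest.mark.parametrize("block_cls,oracle", [
    (CBAMDBlock, cbamd_block_oracle),
    (ImprovedResNetBlock, improved_block_oracle),
    (SMBlock, sm_block_oracle),
])
@pytest.mark.parametrize("out_ch,stride", [(4, 1), (8, 2)])
def test_block_matches_straight_line_oracle(rng, block_cls, oracle, out_ch, stride):
    """Random weights, BN stats off identity: block == naive line-by-line trace."""
    block = block_cls(_tiny_cfg(4, out_ch, stride), rng=rng)
    block.eval()
    for _, m in block.named_modules():
        if hasattr(m, "running_mean"):
            m.weight.data = rng.uniform(0.5, 1.5, m.weight.data.shape).astype(np.float32)
            m.bias.data = rng.normal(0, 0.2, m.bias.data.shape).astype(np.float32)
            m.running_mean = rng.normal(0, 0.2, m.running_mean.shape).astype(np.float32)
            m.running_var = rng.uniform(0.5, 1.5, m.running_var.shape).astype(np.float32)
    x = rng.normal(size=(1, 4, 4, 4)).astype(np.float32)
    out = block(Tensor(x)).data
    ref = oracle(x.astype(np.float64), block)
    np.testing.assert_allclose(out, ref, rtol=1e-3, atol=1e-5)
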