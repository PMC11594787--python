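"""Model assembly: shape contracts, variant grid, baselines, ablation order."""

import itertools

import numpy as np
import pytest

from lmnet.complexity import count_parameters
from lmnet.models import (CANONICAL_DIALS, ModelConfig, StageDials,
                          build_baseline, build_cbamd_resnet, build_lmn,
                          build_variant, tiny_config)
from lmnet.nn import Tensor


TOY = ModelConfig(widths=(8, 16, 32, 64), depths=(1, 1, 1, 1), num_classes=3,
                  stem_width=8,
                  dials=tuple(StageDials(reduction_r=2, branch_hidden=c, branch_reduce=c // 2,
                                         groups_g=2, expansion_t=1.0)
                              for c in (4, 8, 16, 32)))


def test_lmn_logit_shape_contract():
    model = build_lmn(tiny_config(num_classes=7))
    model.eval()
    for n in (1, 5):
        x = np.zeros((n, 3, 64, 64), dtype=np.float32)
        assert model(Tensor(x)).shape == (n, 7)


def test_lmn_rejects_non_rrss():
    with pytest.raises(ValueError):
        build_lmn(ModelConfig(stage_types="SSRR"))
    with pytest.raises(ValueError):
        ModelConfig(stage_types="RRXX")
    with pytest.raises(ValueError):
        ModelConfig(stage_types="RRSS", widths=(66, 128, 256, 512))


def test_build_is_deterministic():
    a = build_lmn(tiny_config(seed=5))
    b = build_lmn(tiny_config(seed=5))
    assert count_parameters(a) == count_parameters(b)
    x = Tensor(np.random.default_rng(0).normal(size=(1, 3, 32, 32)).astype(np.float32))
    a.eval(), b.eval()
    np.testing.assert_array_equal(a(x).data, b(x).data)


def test_variant_rrss_equals_lmn():
    cfg = ModelConfig()
    assert (count_parameters(build_variant("RRSS", cfg))
            == count_parameters(build_lmn(cfg)))


def test_oooo_variant_is_plain_resnet18_topology():
    """OOOO without attention == the standard basic-block ResNet-18 skeleton."""
    net = build_variant("OOOO", ModelConfig(attention_kind="none", num_classes=1000))
    assert count_parameters(net) == count_parameters(build_baseline("resnet18", 1000))


def test_full_variant_grid_builds_and_forwards():
    """All 16 R/S stage-type codes instantiate and map 224 input to logits."""
    x = Tensor(np.zeros((1, 3, 224, 224), dtype=np.float32))
    for code in ("".join(c) for c in itertools.product("RS", repeat=4)):
        net = build_variant(code)
        net.eval()
        assert net(x).shape == (1, 7), code


@pytest.mark.parametrize("kind", ["SE", "ECA", "CBAM", "none"])
def test_attention_swaps_build_and_forward(kind):
    """The attention comparison slots SE/ECA/CBAM into the same skeleton."""
    net = build_variant("RRSS", tiny_config().with_(attention_kind=kind))
    net.eval()
    out = net(Tensor(np.zeros((1, 3, 32, 32), dtype=np.float32)))
    assert out.shape == (1, 4)


def test_toy_parameter_count_matches_closed_form():
    """Layer-by-layer closed-form sum for a small config, computed by hand."""
    net = build_variant("RRSS", TOY)

    def ca_params(c, r=2):
        mid = c // r
        return c * mid + 2 * mid + 2 * mid * c

    def r_block(inp, out, bh, br, identity):
        p = 9 * inp * out + 2 * out                     # conv1 + bn1
        q = out // 4
        p += out * q                                    # branch a
        p += out * bh + 9 * bh * q                      # branch b
        p += out * br + 49 * br + br * q                # branch c
        p += out * q                                    # branch d
        p += ca_params(out) + 2 * out                   # attention + bn2
        if identity:
            p += inp * out + 2 * out
        return p

    def s_block(inp, out, g, identity):
        hid = inp                                       # t = 1
        p = hid * inp // g + 2 * hid                    # expand + bn1
        p += 9 * hid                                    # dw conv
        p += ca_params(hid) + 2 * hid                   # attention + bn2
        p += (hid // g) * out + 2 * out                 # project + bn3
        if identity:
            p += inp * out + 2 * out
        return p

    expect = (7 * 7 * 3 * 8 + 2 * 8                     # stem conv + bn
              + r_block(8, 8, 4, 2, identity=False)
              + r_block(8, 16, 8, 4, identity=True)
              + s_block(16, 32, 2, identity=True)
              + s_block(32, 64, 2, identity=True)
              + 64 * 3 + 3)                             # head
    assert count_parameters(net) == expect


def test_ablation_parameter_ordering():
    """no-CA < with-CA; LMN < ResNet-18 topology with the same head."""
    with_ca = count_parameters(build_lmn())
    without = count_parameters(build_variant("RRSS", ModelConfig(attention_kind="none")))
    resnet_like = count_parameters(build_variant(
        "OOOO", ModelConfig(attention_kind="none")))
    assert without < with_ca < resnet_like


def test_cbamd_resnet_builds():
    net = build_cbamd_resnet(num_classes=7)
    net.eval()
    out = net(Tensor(np.zeros((1, 3, 224, 224), dtype=np.float32)))
    assert out.shape == (1, 7)
    assert count_parameters(net) > 0


def test_baseline_registry_errors():
    with pytest.raises(ValueError, match="resnet18"):
        build_baseline("resnet19")
    with pytest.raises(ValueError, match="not supported"):
        build_baseline("convnext_tiny")
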