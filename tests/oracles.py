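"""Independent straight-line reference implementations used by the tests.

Everything here is deliberately naive plain numpy (explicit loops, no
shared code with the package's compute core) so block/attention outputs
can be checked against a line-by-line execution of their definitions.
"""

from __future__ import annotations

import numpy as np


def conv2d_naive(x, w, b=None, stride=1, padding=0, dilation=1, groups=1):
    """Reference 2-D cross-correlation with explicit loops."""
    n, cin, h, wd = x.shape
    cout, cin_g, kh, kw = w.shape
    xp = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    ho = (h + 2 * padding - (kh - 1) * dilation - 1) // stride + 1
    wo = (wd + 2 * padding - (kw - 1) * dilation - 1) // stride + 1
    out = np.zeros((n, cout, ho, wo), dtype=np.float64)
    cpg_in, cpg_out = cin // groups, cout // groups
    for ni in range(n):
        for co in range(cout):
            g = co // cpg_out
            for yo in range(ho):
                for xo in range(wo):
                    acc = 0.0
                    for ci in range(cin_g):
                        for i in range(kh):
                            for j in range(kw):
                                acc += (xp[ni, g * cpg_in + ci,
                                           yo * stride + i * dilation,
                                           xo * stride + j * dilation]
                                        * w[co, ci, i, j])
                    out[ni, co, yo, xo] = acc
            if b is not None:
                out[ni, co] += b[co]
    return out


def bn_eval(x, gamma, beta, mean, var, eps=1e-5):
    g = gamma.reshape(1, -1, 1, 1)
    b = beta.reshape(1, -1, 1, 1)
    m = mean.reshape(1, -1, 1, 1)
    v = var.reshape(1, -1, 1, 1)
    return g * (x - m) / np.sqrt(v + eps) + b


def relu(x):
    return np.maximum(x, 0)


def sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def maxpool_naive(x, kernel, stride, padding=0):
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)),
                constant_values=-np.inf)
    ho = (h + 2 * padding - kernel) // stride + 1
    wo = (w + 2 * padding - kernel) // stride + 1
    out = np.zeros((n, c, ho, wo))
    for ni in range(n):
        for ci in range(c):
            for yo in range(ho):
                for xo in range(wo):
                    out[ni, ci, yo, xo] = xp[ni, ci,
                                             yo * stride:yo * stride + kernel,
                                             xo * stride:xo * stride + kernel].max()
    return out


def shuffle_naive(x, g):
    """Channel shuffle by explicit index arithmetic."""
    n, c, h, w = x.shape
    out = np.empty_like(x)
    cpg = c // g
    for i in range(c):
        # source channel i lands at position (i % cpg) * g + i // cpg
        out[:, (i % cpg) * g + i // cpg] = x[:, i]
    return out


def _conv_mod(x, conv):
    return conv2d_naive(
        x, conv.weight.data.astype(np.float64),
        None if conv.bias is None else conv.bias.data.astype(np.float64),
        conv.stride, conv.padding, conv.dilation, conv.groups)


def _bn_mod(x, bn):
    return bn_eval(x, bn.weight.data, bn.bias.data, bn.running_mean,
                   bn.running_var, bn.eps)


def coordinate_attention_oracle(x, ca):
    """Straight-line coordinate attention using the module's weights."""
    n, c, h, w = x.shape
    pool_h = x.mean(axis=3, keepdims=True)                  # (N,C,H,1)
    pool_w = x.mean(axis=2, keepdims=True)                  # (N,C,1,W)
    y = np.concatenate([pool_h, pool_w.transpose(0, 1, 3, 2)], axis=2)
    y = relu(_bn_mod(_conv_mod(y, ca.conv_shared), ca.bn))
    a_h = sigmoid(_conv_mod(y[:, :, :h, :], ca.conv_h))
    a_w = sigmoid(_conv_mod(y[:, :, h:, :].transpose(0, 1, 3, 2), ca.conv_w))
    return x * a_h * a_w


def se_oracle(x, se):
    s = x.mean(axis=(2, 3), keepdims=True)
    g = sigmoid(_conv_mod(relu(_conv_mod(s, se.fc1)), se.fc2))
    return x * g


def cbam_oracle(x, cbam):
    cg = cbam.channel_gate
    avg = x.mean(axis=(2, 3), keepdims=True)
    mx = x.max(axis=(2, 3), keepdims=True)
    shared = lambda s: _conv_mod(relu(_conv_mod(s, cg.fc1)), cg.fc2)
    out = x * sigmoid(shared(avg) + shared(mx))
    savg = out.mean(axis=1, keepdims=True)
    smax = out.max(axis=1, keepdims=True)
    gate = sigmoid(_conv_mod(np.concatenate([savg, smax], axis=1),
                             cbam.spatial_gate.conv))
    return out * gate


def _identity_path(x, block):
    down = block.downsample
    if not hasattr(down, "layers"):        # Identity
        return x
    conv, bn = down.layers
    return _bn_mod(_conv_mod(x, conv), bn)


def cbamd_block_oracle(x, block):
    """Line-by-line execution of the CBAMD block definition."""
    identity = _identity_path(x, block)
    out = relu(_bn_mod(_conv_mod(x, block.conv1), block.bn1))
    out = _bn_mod(_conv_mod(out, block.conv2), block.bn2)
    out = cbam_oracle(out, block.cbam)
    return relu(out + identity)


def inception_oracle(x, unit):
    a = _conv_mod(x, unit.branch_a)
    b = _conv_mod(_conv_mod(x, unit.branch_b.layers[0]), unit.branch_b.layers[1])
    c1 = _conv_mod(x, unit.branch_c.layers[0])
    c2 = _conv_mod(c1, unit.branch_c.layers[1])
    c = _conv_mod(c2, unit.branch_c.layers[2])
    d = _conv_mod(maxpool_naive(x, 3, 1, 1), unit.branch_d.layers[1])
    return np.concatenate([a, b, c, d], axis=1)


def improved_block_oracle(x, block):
    """Line-by-line execution of the improved residual block definition."""
    identity = _identity_path(x, block)
    out = relu(_bn_mod(_conv_mod(x, block.conv1), block.bn1))
    out = inception_oracle(out, block.inception)
    if hasattr(block.attention, "conv_shared"):
        out = coordinate_attention_oracle(out, block.attention)
    out = _bn_mod(out, block.bn2)
    return relu(out + identity)


def sm_block_oracle(x, block):
    """Line-by-line execution of the shuffled bottleneck block definition."""
    identity = _identity_path(x, block)
    out = relu(_bn_mod(_conv_mod(x, block.expand), block.bn1))
    out = _conv_mod(out, block.dwconv)
    if hasattr(block.attention, "conv_shared"):
        out = coordinate_attention_oracle(out, block.attention)
    out = _bn_mod(out, block.bn2)
    out = _bn_mod(_conv_mod(out, block.project), block.bn3)
    out = shuffle_naive(out, block.groups_g)
    return relu(out + identity)
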