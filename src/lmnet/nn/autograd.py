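"""Minimal reverse-mode autodiff over numpy arrays.

A :class:`Tensor` wraps a float32 ``numpy`` array and remembers the
operations that produced it; :meth:`Tensor.backward` walks the tape in
reverse topological order.  Only the operations needed by the image
classification stack are provided (2-D convolution via im2col, pooling,
batch normalisation, elementwise arithmetic, matmul, softmax loss).
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Parameter"]


def _as_array(x) -> np.ndarray:
    if isinstance(x, np.ndarray):
        return x.astype(np.float32, copy=False)
    return np.asarray(x, dtype=np.float32)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_array(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    # -- graph plumbing ------------------------------------------------
    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=np.float32))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic ----------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __sub__(self, other):
        return add(self, mul(other, -1.0))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __neg__(self):
        return mul(self, -1.0)

    def __getitem__(self, idx):
        return getitem(self, idx)

    def reshape(self, *shape):
        return reshape(self, shape)

    def transpose(self, axes):
        return transpose(self, axes)


class Parameter(Tensor):
    """A tensor registered as trainable by the module system."""

    __slots__ = ()

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _needs_grad(*ts: Tensor) -> bool:
    return any(t.requires_grad or t._parents for t in ts)


def _make(data, parents, backward, track: bool) -> Tensor:
    out = Tensor(data)
    if track:
        out._parents = tuple(parents)
        out._backward = backward
    return out


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce gradient ``g`` back to ``shape`` after numpy broadcasting."""
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g


# ---------------------------------------------------------------------
# primitive operations
# ---------------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    track = _needs_grad(a, b)

    def backward(g):
        if a.requires_grad or a._parents:
            a._accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad or b._parents:
            b._accumulate(_unbroadcast(g, b.data.shape))

    return _make(a.data + b.data, (a, b), backward, track)


def mul(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    track = _needs_grad(a, b)

    def backward(g):
        if a.requires_grad or a._parents:
            a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad or b._parents:
            b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    return _make(a.data * b.data, (a, b), backward, track)


def matmul(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    track = _needs_grad(a, b)

    def backward(g):
        if a.requires_grad or a._parents:
            a._accumulate(g @ b.data.T)
        if b.requires_grad or b._parents:
            b._accumulate(a.data.T @ g)

    return _make(a.data @ b.data, (a, b), backward, track)


def relu(x) -> Tensor:
    x = _wrap(x)
    mask = x.data > 0
    track = _needs_grad(x)

    def backward(g):
        x._accumulate(g * mask)

    return _make(x.data * mask, (x,), backward, track)


def sigmoid(x) -> Tensor:
    x = _wrap(x)
    out_data = 1.0 / (1.0 + np.exp(-x.data))
    track = _needs_grad(x)

    def backward(g):
        x._accumulate(g * out_data * (1.0 - out_data))

    return _make(out_data, (x,), backward, track)


def mean(x, axis, keepdims: bool = False) -> Tensor:
    x = _wrap(x)
    axis = tuple(axis) if isinstance(axis, (tuple, list)) else (axis,)
    n = int(np.prod([x.data.shape[a] for a in axis]))
    out_data = x.data.mean(axis=axis, keepdims=keepdims)
    track = _needs_grad(x)

    def backward(g):
        if not keepdims:
            g = np.expand_dims(g, axis)
        x._accumulate(np.broadcast_to(g, x.data.shape) / n)

    return _make(out_data, (x,), backward, track)


def sum_(x, axis=None, keepdims: bool = False) -> Tensor:
    x = _wrap(x)
    out_data = x.data.sum(axis=axis, keepdims=keepdims)
    track = _needs_grad(x)

    def backward(g):
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        x._accumulate(np.broadcast_to(g, x.data.shape).copy())

    return _make(out_data, (x,), backward, track)


def reshape(x, shape) -> Tensor:
    x = _wrap(x)
    track = _needs_grad(x)

    def backward(g):
        x._accumulate(g.reshape(x.data.shape))

    return _make(x.data.reshape(shape), (x,), backward, track)


def transpose(x, axes) -> Tensor:
    x = _wrap(x)
    inv = np.argsort(axes)
    track = _needs_grad(x)

    def backward(g):
        x._accumulate(g.transpose(inv))

    return _make(x.data.transpose(axes), (x,), backward, track)


def concat(tensors, axis: int = 1) -> Tensor:
    tensors = [_wrap(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)
    track = _needs_grad(*tensors)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            if t.requires_grad or t._parents:
                t._accumulate(g[tuple(sl)])

    return _make(np.concatenate([t.data for t in tensors], axis=axis),
                 tensors, backward, track)


def getitem(x, idx) -> Tensor:
    x = _wrap(x)
    track = _needs_grad(x)

    def backward(g):
        full = np.zeros_like(x.data)
        np.add.at(full, idx, g)
        x._accumulate(full)

    return _make(x.data[idx], (x,), backward, track)


# ---------------------------------------------------------------------
# convolution / pooling
# ---------------------------------------------------------------------

def _im2col(xp: np.ndarray, kh: int, kw: int, stride: int, dilation: int):
    """View of all sliding windows: (N, C, Ho, Wo, kh, kw)."""
    n, c, h, w = xp.shape
    ho = (h - (kh - 1) * dilation - 1) // stride + 1
    wo = (w - (kw - 1) * dilation - 1) // stride + 1
    sn, sc, sh, sw = xp.strides
    return np.lib.stride_tricks.as_strided(
        xp,
        shape=(n, c, ho, wo, kh, kw),
        strides=(sn, sc, sh * stride, sw * stride, sh * dilation, sw * dilation),
        writeable=False,
    )


def conv2d(x, weight, bias=None, stride: int = 1, padding: int = 0,
           dilation: int = 1, groups: int = 1) -> Tensor:
    """2-D cross-correlation with groups and dilation.

    ``weight`` has shape (Cout, Cin/groups, kh, kw).
    """
    x, weight = _wrap(x), _wrap(weight)
    if bias is not None:
        bias = _wrap(bias)
    n, cin, h, w = x.data.shape
    cout, cin_g, kh, kw = weight.data.shape
    g = groups
    if cin != cin_g * g:
        raise ValueError(f"conv2d: {cin} input channels, weight expects {cin_g * g}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    windows = _im2col(xp, kh, kw, stride, dilation)
    _, _, ho, wo, _, _ = windows.shape
    # (g, N*Ho*Wo, Cin/g*kh*kw)
    cols = (windows.reshape(n, g, cin_g, ho, wo, kh, kw)
            .transpose(1, 0, 3, 4, 2, 5, 6)
            .reshape(g, n * ho * wo, cin_g * kh * kw))
    wmat = weight.data.reshape(g, cout // g, cin_g * kh * kw)
    out = np.matmul(cols, wmat.transpose(0, 2, 1))        # (g, N*Ho*Wo, Cout/g)
    out = (out.reshape(g, n, ho, wo, cout // g)
           .transpose(1, 0, 4, 2, 3)
           .reshape(n, cout, ho, wo))
    if bias is not None:
        out = out + bias.data.reshape(1, cout, 1, 1)
    parents = (x, weight) if bias is None else (x, weight, bias)
    track = _needs_grad(*parents)

    def backward(grad):
        go = (grad.reshape(n, g, cout // g, ho, wo)
              .transpose(1, 0, 3, 4, 2)
              .reshape(g, n * ho * wo, cout // g))
        if weight.requires_grad or weight._parents:
            gw = np.matmul(go.transpose(0, 2, 1), cols)   # (g, Cout/g, Cin/g*kh*kw)
            weight._accumulate(gw.reshape(cout, cin_g, kh, kw))
        if bias is not None and (bias.requires_grad or bias._parents):
            bias._accumulate(grad.sum(axis=(0, 2, 3)))
        if x.requires_grad or x._parents:
            gcols = np.matmul(go, wmat)                   # (g, N*Ho*Wo, Cin/g*kh*kw)
            gwin = (gcols.reshape(g, n, ho, wo, cin_g, kh, kw)
                    .transpose(1, 0, 4, 2, 3, 5, 6)
                    .reshape(n, cin, ho, wo, kh, kw))
            gxp = np.zeros_like(xp)
            for i in range(kh):
                hi = i * dilation
                for j in range(kw):
                    wj = j * dilation
                    gxp[:, :, hi:hi + ho * stride:stride,
                        wj:wj + wo * stride:stride] += gwin[:, :, :, :, i, j]
            if padding:
                gxp = gxp[:, :, padding:-padding, padding:-padding]
            x._accumulate(gxp)

    return _make(out, parents, backward, track)


def max_pool2d(x, kernel: int, stride: int, padding: int = 0) -> Tensor:
    x = _wrap(x)
    n, c, h, w = x.data.shape
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)),
                constant_values=-np.inf)
    windows = _im2col(xp, kernel, kernel, stride, 1)
    _, _, ho, wo, _, _ = windows.shape
    flat = windows.reshape(n, c, ho, wo, kernel * kernel)
    arg = flat.argmax(axis=-1)
    out = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]
    track = _needs_grad(x)

    def backward(g):
        gxp = np.zeros_like(xp)
        ii, jj = np.divmod(arg, kernel)
        nidx, cidx, hidx, widx = np.indices((n, c, ho, wo), sparse=False)
        np.add.at(gxp, (nidx, cidx, hidx * stride + ii, widx * stride + jj), g)
        if padding:
            gxp = gxp[:, :, padding:-padding, padding:-padding]
        x._accumulate(gxp)

    return _make(out, (x,), backward, track)


def batch_norm(x, gamma, beta, running_mean: np.ndarray, running_var: np.ndarray,
               training: bool, momentum: float = 0.1, eps: float = 1e-5) -> Tensor:
    """Batch normalisation over (N, H, W) per channel; updates running stats in place."""
    x, gamma, beta = _wrap(x), _wrap(gamma), _wrap(beta)
    axes = (0, 2, 3)
    if training:
        m = x.data.mean(axis=axes)
        v = x.data.var(axis=axes)
        cnt = x.data.size // x.data.shape[1]
        running_mean *= 1 - momentum
        running_mean += momentum * m
        running_var *= 1 - momentum
        running_var += momentum * (v * cnt / max(cnt - 1, 1))
    else:
        m, v = running_mean, running_var
    inv = 1.0 / np.sqrt(v + eps)
    xhat = (x.data - m.reshape(1, -1, 1, 1)) * inv.reshape(1, -1, 1, 1)
    out = gamma.data.reshape(1, -1, 1, 1) * xhat + beta.data.reshape(1, -1, 1, 1)
    track = _needs_grad(x, gamma, beta)

    def backward(g):
        if gamma.requires_grad or gamma._parents:
            gamma._accumulate((g * xhat).sum(axis=axes))
        if beta.requires_grad or beta._parents:
            beta._accumulate(g.sum(axis=axes))
        if x.requires_grad or x._parents:
            gxh = g * gamma.data.reshape(1, -1, 1, 1)
            if training:
                nn = x.data.size // x.data.shape[1]
                gsum = gxh.sum(axis=axes, keepdims=True)
                gxsum = (gxh * xhat).sum(axis=axes, keepdims=True)
                gx = (gxh - gsum / nn - xhat * gxsum / nn) * inv.reshape(1, -1, 1, 1)
            else:
                gx = gxh * inv.reshape(1, -1, 1, 1)
            x._accumulate(gx)

    return _make(out, (x, gamma, beta), backward, track)


def log_softmax(x) -> Tensor:
    """Row-wise log-softmax for (N, K) logits."""
    x = _wrap(x)
    shifted = x.data - x.data.max(axis=1, keepdims=True)
    lse = np.log(np.exp(shifted).sum(axis=1, keepdims=True))
    out = shifted - lse
    track = _needs_grad(x)

    def backward(g):
        softmax = np.exp(out)
        x._accumulate(g - softmax * g.sum(axis=1, keepdims=True))

    return _make(out, (x,), backward, track)
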