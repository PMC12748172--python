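"""Differentiable operations beyond basic arithmetic.

All functions accept and return :class:`~vesseltext.autodiff.tensor.Tensor`
and register their own backward rules.  Convolution uses an im2col/col2im
pair so the heavy lifting is a single BLAS matmul.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, as_tensor

__all__ = [
    "relu",
    "sigmoid",
    "exp",
    "log",
    "sqrt",
    "softmax",
    "concat",
    "conv2d",
    "max_pool2d",
    "avg_pool2d",
    "upsample_nearest",
]


def relu(x: Tensor) -> Tensor:
    x = as_tensor(x)
    mask = x.data > 0

    def backward(g):
        x._accumulate(g * mask)

    return Tensor._make(np.where(mask, x.data, 0.0), (x,), backward)


def sigmoid(x: Tensor) -> Tensor:
    x = as_tensor(x)
    # numerically stable two-sided formulation
    out = np.empty_like(x.data)
    pos = x.data >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x.data[pos]))
    e = np.exp(x.data[~pos])
    out[~pos] = e / (1.0 + e)

    def backward(g):
        x._accumulate(g * out * (1.0 - out))

    return Tensor._make(out, (x,), backward)


def exp(x: Tensor) -> Tensor:
    x = as_tensor(x)
    out = np.exp(x.data)

    def backward(g):
        x._accumulate(g * out)

    return Tensor._make(out, (x,), backward)


def log(x: Tensor) -> Tensor:
    x = as_tensor(x)

    def backward(g):
        x._accumulate(g / x.data)

    return Tensor._make(np.log(x.data), (x,), backward)


def sqrt(x: Tensor) -> Tensor:
    x = as_tensor(x)
    out = np.sqrt(x.data)

    def backward(g):
        x._accumulate(g * 0.5 / out)

    return Tensor._make(out, (x,), backward)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    x = as_tensor(x)
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    out = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        dot = (g * out).sum(axis=axis, keepdims=True)
        x._accumulate(out * (g - dot))

    return Tensor._make(out, (x,), backward)


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    return Tensor._make(
        np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), backward
    )


# --------------------------------------------------------------------- conv2d
def _im2col(x: np.ndarray, kh: int, kw: int, pad: int) -> np.ndarray:
    """(B,C,H,W) -> (B, C*kh*kw, H*W) patches for stride-1 convolution."""
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    b, c, h, w = x.shape
    oh, ow = h - kh + 1, w - kw + 1
    win = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(2, 3))
    # win: (B, C, oh, ow, kh, kw) -> (B, C, kh, kw, oh, ow)
    win = win.transpose(0, 1, 4, 5, 2, 3)
    return np.ascontiguousarray(win).reshape(b, c * kh * kw, oh * ow), (oh, ow)


def _col2im(cols: np.ndarray, x_shape, kh: int, kw: int, pad: int) -> np.ndarray:
    """Adjoint of :func:`_im2col` (scatter-add patches back)."""
    b, c, h, w = x_shape
    hp, wp = h + 2 * pad, w + 2 * pad
    oh, ow = hp - kh + 1, wp - kw + 1
    cols = cols.reshape(b, c, kh, kw, oh, ow)
    out = np.zeros((b, c, hp, wp))
    for i in range(kh):
        for j in range(kw):
            out[:, :, i : i + oh, j : j + ow] += cols[:, :, i, j]
    if pad:
        out = out[:, :, pad:-pad, pad:-pad]
    return out


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None, padding: int = 0) -> Tensor:
    """Stride-1 2-D convolution (cross-correlation) on (B,C,H,W) input."""
    x, weight = as_tensor(x), as_tensor(weight)
    o, c, kh, kw = weight.shape
    b = x.shape[0]
    cols, (oh, ow) = _im2col(x.data, kh, kw, padding)
    wmat = weight.data.reshape(o, c * kh * kw)
    out = np.matmul(wmat, cols).reshape(b, o, oh, ow)
    if bias is not None:
        out = out + bias.data.reshape(1, o, 1, 1)

    parents = (x, weight) + ((bias,) if bias is not None else ())

    def backward(g):
        gmat = g.reshape(b, o, oh * ow)
        if weight.requires_grad:
            gw = np.einsum("bop,bkp->ok", gmat, cols)
            weight._accumulate(gw.reshape(o, c, kh, kw))
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gcols = np.matmul(wmat.T, gmat)
            x._accumulate(_col2im(gcols, x.shape, kh, kw, padding))

    return Tensor._make(out, parents, backward)


# -------------------------------------------------------------------- pooling
def max_pool2d(x: Tensor, k: int = 2) -> Tensor:
    x = as_tensor(x)
    b, c, h, w = x.shape
    if h % k or w % k:
        raise ValueError(f"spatial dims {(h, w)} not divisible by pool size {k}")
    oh, ow = h // k, w // k
    r = x.data.reshape(b, c, oh, k, ow, k).transpose(0, 1, 2, 4, 3, 5)
    r = r.reshape(b, c, oh, ow, k * k)
    idx = r.argmax(axis=-1)
    out = np.take_along_axis(r, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        gr = np.zeros((b, c, oh, ow, k * k))
        np.put_along_axis(gr, idx[..., None], g[..., None], axis=-1)
        gr = gr.reshape(b, c, oh, ow, k, k).transpose(0, 1, 2, 4, 3, 5)
        x._accumulate(gr.reshape(b, c, h, w))

    return Tensor._make(out, (x,), backward)


def avg_pool2d(x: Tensor, k: int = 2) -> Tensor:
    x = as_tensor(x)
    b, c, h, w = x.shape
    if h % k or w % k:
        raise ValueError(f"spatial dims {(h, w)} not divisible by pool size {k}")
    oh, ow = h // k, w // k
    out = x.data.reshape(b, c, oh, k, ow, k).mean(axis=(3, 5))

    def backward(g):
        gx = np.repeat(np.repeat(g, k, axis=2), k, axis=3) / (k * k)
        x._accumulate(gx)

    return Tensor._make(out, (x,), backward)


def upsample_nearest(x: Tensor, factor: int = 2) -> Tensor:
    x = as_tensor(x)
    out = np.repeat(np.repeat(x.data, factor, axis=2), factor, axis=3)
    b, c, h, w = x.shape

    def backward(g):
        gr = g.reshape(b, c, h, factor, w, factor).sum(axis=(3, 5))
        x._accumulate(gr)

    return Tensor._make(out, (x,), backward)
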