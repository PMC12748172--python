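"""Pixel-level attention applied at encoder→decoder skip connections.

Wiring (committed, and pinned by the tests):

* channel branch — global-average and global-max descriptors each pass
  through a shared bottleneck perceptron, are summed and sigmoid-squashed
  into per-channel weights that scale the input;
* spatial branch — per-pixel channel mean and max are stacked and convolved
  (7x7) into a sigmoid map that scales positions of the input;
* merge — the two attended maps are concatenated, projected back to C
  channels by a 1x1 convolution, and added to the input (residual).

With all parameters at zero the merge path vanishes and the block is exactly
the identity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Conv2d, Module, Parameter, Tensor
from .autodiff import functional as F
from .se_attention import bottleneck_dim

__all__ = ["PLAMParams", "plam_apply", "PLAMBlock", "plam_param_count"]

SPATIAL_KERNEL = 7  # CBAM convention; padding keeps shape


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class PLAMParams:
    """Weights for one PLAM block over C channels.

    mlp_w1: (C/r, C); mlp_w2: (C, C/r) — shared channel perceptron (no bias).
    spatial_kernel: (2, 7, 7) kernel mapping stacked mean/max maps to logits;
    spatial_bias: scalar.
    merge_weight: (C, 2C, 1, 1) as a (C, 2C) matrix; merge_bias: (C,).
    """

    mlp_w1: np.ndarray
    mlp_w2: np.ndarray
    spatial_kernel: np.ndarray
    spatial_bias: float
    merge_weight: np.ndarray
    merge_bias: np.ndarray

    def __post_init__(self):
        self.mlp_w1 = np.asarray(self.mlp_w1, dtype=float)
        self.mlp_w2 = np.asarray(self.mlp_w2, dtype=float)
        self.spatial_kernel = np.asarray(self.spatial_kernel, dtype=float)
        self.merge_weight = np.asarray(self.merge_weight, dtype=float)
        self.merge_bias = np.asarray(self.merge_bias, dtype=float)
        c = self.channels
        if self.mlp_w1.shape[1] != c or self.mlp_w2.shape != self.mlp_w1.shape[::-1]:
            raise ValueError("inconsistent channel perceptron shapes")
        if self.spatial_kernel.shape[0] != 2:
            raise ValueError("spatial kernel must take 2 stacked maps")
        if self.merge_weight.shape != (c, 2 * c) or self.merge_bias.shape != (c,):
            raise ValueError("inconsistent merge projection shapes")
        for arr in (self.mlp_w1, self.mlp_w2, self.spatial_kernel,
                    self.merge_weight, self.merge_bias):
            if not np.isfinite(arr).all():
                raise ValueError("parameters must be finite")

    @property
    def channels(self) -> int:
        return self.mlp_w2.shape[0]

    @classmethod
    def zeros(cls, channels: int, reduction: int = 16) -> "PLAMParams":
        hidden = bottleneck_dim(channels, reduction)
        k = SPATIAL_KERNEL
        return cls(np.zeros((hidden, channels)), np.zeros((channels, hidden)),
                   np.zeros((2, k, k)), 0.0,
                   np.zeros((channels, 2 * channels)), np.zeros(channels))

    @classmethod
    def init(cls, channels: int, rng: np.random.Generator, reduction: int = 16) -> "PLAMParams":
        p = cls.zeros(channels, reduction)
        hidden = p.mlp_w1.shape[0]
        k = SPATIAL_KERNEL
        b1, b2 = 1.0 / np.sqrt(channels), 1.0 / np.sqrt(hidden)
        bs = 1.0 / np.sqrt(2 * k * k)
        bm = 1.0 / np.sqrt(2 * channels)
        return cls(rng.uniform(-b1, b1, p.mlp_w1.shape),
                   rng.uniform(-b2, b2, p.mlp_w2.shape),
                   rng.uniform(-bs, bs, (2, k, k)), 0.0,
                   rng.uniform(-bm, bm, p.merge_weight.shape), np.zeros(channels))


def _conv2d_same(img: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Single-map stride-1 'same' cross-correlation, summed over input maps."""
    from scipy.ndimage import correlate

    out = np.zeros(img.shape[1:])
    for ch in range(kernel.shape[0]):
        out += correlate(img[ch], kernel[ch], mode="constant", cval=0.0)
    return out


def plam_apply(skip: np.ndarray, p: PLAMParams) -> np.ndarray:
    """Apply the block to a single (C,H,W) map (reference numpy path)."""
    skip = np.asarray(skip, dtype=float)
    if skip.ndim != 3:
        raise ValueError("skip map must be rank-3 (C,H,W)")
    if skip.shape[0] != p.channels:
        raise ValueError(f"expected {p.channels} channels, got {skip.shape[0]}")

    gap = skip.mean(axis=(1, 2))
    gmp = skip.max(axis=(1, 2))
    mlp = lambda v: p.mlp_w2 @ np.maximum(p.mlp_w1 @ v, 0.0)
    ch_scale = _sigmoid(mlp(gap) + mlp(gmp))                  # (C,)
    ca = ch_scale[:, None, None] * skip

    stacked = np.stack([skip.mean(axis=0), skip.max(axis=0)])  # (2,H,W)
    sp_scale = _sigmoid(_conv2d_same(stacked, p.spatial_kernel) + p.spatial_bias)
    sa = sp_scale[None, :, :] * skip

    both = np.concatenate([ca, sa], axis=0)                    # (2C,H,W)
    merged = np.einsum("oc,chw->ohw", p.merge_weight, both) + p.merge_bias[:, None, None]
    return merged + skip


def plam_param_count(channels: int, reduction: int = 16) -> int:
    hidden = bottleneck_dim(channels, reduction)
    k = SPATIAL_KERNEL
    return (2 * channels * hidden          # shared perceptron
            + 2 * k * k + 1                # spatial conv + bias
            + 2 * channels * channels + channels)  # merge projection


class _ChannelMax(Module):
    """max over an axis with subgradient routed to the argmax."""

    def __init__(self, axis: int):
        super().__init__()
        self.axis = axis

    def forward(self, x: Tensor) -> Tensor:
        axis = self.axis
        idx = np.expand_dims(x.data.argmax(axis=axis), axis)
        out = np.take_along_axis(x.data, idx, axis=axis)

        def backward(g):
            gx = np.zeros_like(x.data)
            np.put_along_axis(gx, idx, g, axis=axis)
            x._accumulate(gx)

        return Tensor._make(out, (x,), backward)


class PLAMBlock(Module):
    """Differentiable PLAM for batched (B,C,H,W) tensors."""

    def __init__(self, channels: int, rng: np.random.Generator, reduction: int = 16):
        super().__init__()
        self.channels = channels
        hidden = bottleneck_dim(channels, reduction)
        b1, b2 = 1.0 / np.sqrt(channels), 1.0 / np.sqrt(hidden)
        self.mlp_w1 = Parameter(rng.uniform(-b1, b1, (hidden, channels)))
        self.mlp_w2 = Parameter(rng.uniform(-b2, b2, (channels, hidden)))
        self.spatial = Conv2d(2, 1, SPATIAL_KERNEL, rng)
        self.merge = Conv2d(2 * channels, channels, 1, rng)
        self._max_hw = _ChannelMax(axis=1)

    def forward(self, x: Tensor) -> Tensor:
        b, c, h, w = x.shape
        gap = x.mean(axis=(2, 3))                               # (B,C)
        flat = x.reshape(b, c, h * w)
        gmp = _ChannelMax(axis=2)(flat).reshape(b, c)
        mlp = lambda v: F.relu(v @ self.mlp_w1.transpose(1, 0)) @ self.mlp_w2.transpose(1, 0)
        ch_scale = F.sigmoid(mlp(gap) + mlp(gmp)).reshape(b, c, 1, 1)
        ca = x * ch_scale

        px_mean = x.mean(axis=1, keepdims=True)                 # (B,1,H,W)
        px_max = self._max_hw(x)                                # (B,1,H,W)
        sp_scale = F.sigmoid(self.spatial(F.concat([px_mean, px_max], axis=1)))
        sa = x * sp_scale

        merged = self.merge(F.concat([ca, sa], axis=1))
        return merged + x
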