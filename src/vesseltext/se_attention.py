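"""Squeeze-and-Excitation channel attention.

The block rescales each channel of a feature map by a learned weight in
(0,1): channels are pooled to a global descriptor (*squeeze*), passed through
a two-layer bottleneck perceptron with a sigmoid (*excite*), and the
resulting weights multiply the corresponding channels (*recalibrate*).

Two surfaces are provided: a pure-numpy functional API operating on
``(C, H, W)`` arrays (used directly by tests and oracles), and the
differentiable :class:`SEBlock` module used inside the model, which applies
the identical arithmetic to batched ``(B, C, H, W)`` tensors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Module, Parameter, Tensor
from .autodiff import functional as F

__all__ = ["SEParams", "squeeze", "excite", "recalibrate", "se_block", "SEBlock",
           "bottleneck_dim", "se_param_count"]

DEFAULT_REDUCTION = 16


def bottleneck_dim(channels: int, reduction: int = DEFAULT_REDUCTION) -> int:
    """Hidden width of the excitation perceptron: floor(C/r), clamped to >= 1."""
    if channels < 1 or reduction < 1:
        raise ValueError("channels and reduction must be positive")
    return max(channels // reduction, 1)


def se_param_count(channels: int, reduction: int = DEFAULT_REDUCTION) -> int:
    """Number of learnable scalars in one SE block (two bias-free FC layers)."""
    hidden = bottleneck_dim(channels, reduction)
    return 2 * channels * hidden


@dataclass
class SEParams:
    """Weights of the excitation perceptron (no biases)."""

    w1: np.ndarray  # (C/r, C)
    w2: np.ndarray  # (C, C/r)

    def __post_init__(self):
        self.w1 = np.asarray(self.w1, dtype=float)
        self.w2 = np.asarray(self.w2, dtype=float)
        if self.w1.ndim != 2 or self.w2.ndim != 2:
            raise ValueError("w1 and w2 must be matrices")
        if self.w1.shape[::-1] != self.w2.shape:
            raise ValueError(f"inconsistent shapes: w1 {self.w1.shape}, w2 {self.w2.shape}")
        if not (np.isfinite(self.w1).all() and np.isfinite(self.w2).all()):
            raise ValueError("weights must be finite")

    @property
    def channels(self) -> int:
        return self.w1.shape[1]

    @classmethod
    def init(cls, channels: int, reduction: int = DEFAULT_REDUCTION,
             rng: np.random.Generator | None = None) -> "SEParams":
        rng = rng or np.random.default_rng()
        hidden = bottleneck_dim(channels, reduction)
        b1 = 1.0 / np.sqrt(channels)
        b2 = 1.0 / np.sqrt(hidden)
        return cls(w1=rng.uniform(-b1, b1, (hidden, channels)),
                   w2=rng.uniform(-b2, b2, (channels, hidden)))


def _check_map(u: np.ndarray) -> np.ndarray:
    u = np.asarray(u, dtype=float)
    if u.ndim != 3:
        raise ValueError(f"feature map must be rank-3 (C,H,W), got rank {u.ndim}")
    if 0 in u.shape:
        raise ValueError("feature map has empty extent")
    if not np.isfinite(u).all():
        raise ValueError("feature map contains non-finite values")
    return u


def squeeze(u: np.ndarray) -> np.ndarray:
    """Global average pooling: one descriptor per channel."""
    u = _check_map(u)
    return u.mean(axis=(1, 2))


def excite(z: np.ndarray, p: SEParams) -> np.ndarray:
    """sigmoid(W2 . relu(W1 . z)) — per-channel weights in (0,1)."""
    z = np.asarray(z, dtype=float)
    if z.ndim != 1 or z.shape[0] != p.channels:
        raise ValueError(f"descriptor length {z.shape} does not match {p.channels} channels")
    logits = p.w2 @ np.maximum(p.w1 @ z, 0.0)
    return 1.0 / (1.0 + np.exp(-logits))


def recalibrate(u: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Scale each channel of `u` by the matching entry of `s`."""
    u = _check_map(u)
    s = np.asarray(s, dtype=float)
    if s.ndim != 1 or s.shape[0] != u.shape[0]:
        raise ValueError(f"weight length {s.shape} does not match {u.shape[0]} channels")
    return s[:, None, None] * u


def se_block(u: np.ndarray, p: SEParams) -> np.ndarray:
    """Full squeeze → excite → recalibrate pass."""
    return recalibrate(u, excite(squeeze(u), p))


class SEBlock(Module):
    """Differentiable SE block for batched (B,C,H,W) tensors."""

    def __init__(self, channels: int, rng: np.random.Generator,
                 reduction: int = DEFAULT_REDUCTION):
        super().__init__()
        self.channels = channels
        p = SEParams.init(channels, reduction, rng)
        self.w1 = Parameter(p.w1)
        self.w2 = Parameter(p.w2)

    def forward(self, u: Tensor) -> Tensor:
        b, c, h, w = u.shape
        z = u.mean(axis=(2, 3))                       # (B, C)
        hid = F.relu(z @ self.w1.transpose(1, 0))     # (B, C/r)
        s = F.sigmoid(hid @ self.w2.transpose(1, 0))  # (B, C)
        return u * s.reshape(b, c, 1, 1)
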