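"""Assembly of the dual-branch segmentation model.

CNN branch: U-shaped encoder/decoder with optional SE blocks after the
convolution stack of each encoder stage (``down``), each decoder stage
(``up``) or both (``all``), and PLAM at every skip connection.  Transformer
branch: token-space U over the encoder's level-matched features, fused with
the projected text embedding at its entry and gated per configuration.  The
branch's per-level outputs re-enter the decoder by concatenation followed by
a 1x1 projection.  A 1-channel sigmoid head produces the mask probabilities.
"""

from __future__ import annotations

import numpy as np

from ..autodiff import Conv2d, Module, ModuleList, Tensor
from ..autodiff import functional as F
from ..errors import ConfigError
from ..gated_transformer import PATCH, VitBranch, gate_param_count
from ..plam import PLAMBlock
from ..se_attention import SEBlock, se_param_count
from .config import ModelConfig

__all__ = ["SegmentationModel", "build_model", "expected_se_params", "expected_gate_params"]


class DoubleConv(Module):
    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        super().__init__()
        self.c1 = Conv2d(in_ch, out_ch, 3, rng)
        self.c2 = Conv2d(out_ch, out_ch, 3, rng)

    def forward(self, x: Tensor) -> Tensor:
        return F.relu(self.c2(F.relu(self.c1(x))))


class SegmentationModel(Module):
    def __init__(self, cfg: ModelConfig, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        self.cfg = cfg
        ch = cfg.encoder_channels
        d = cfg.depth
        h, w = cfg.input_size
        if h != w:
            # token grids are square; rectangular inputs would need per-axis edges
            raise ConfigError("input_size must be square")

        self.enc = ModuleList([DoubleConv(1 if i == 0 else ch[i - 1], ch[i], rng)
                               for i in range(d)])
        self.se_down = ModuleList([
            SEBlock(ch[i], rng, cfg.se_reduction) if cfg.se_placement in ("down", "all") else Module()
            for i in range(d)])
        self.plam = ModuleList([PLAMBlock(ch[i], rng) for i in range(d - 1)])

        grid_edges = [(h // 2**i) // PATCH for i in range(d)]
        if grid_edges[-1] < 1:
            raise ConfigError("input too small for the configured depth")
        self.vit = VitBranch(ch, grid_edges, cfg.vit_dim, cfg.heads, rng,
                             text_dim=cfg.text_dim, gated=cfg.gating_enabled,
                             granularity=cfg.gate_granularity,
                             layers_per_level=cfg.vit_depth)

        # bottleneck fusion: [bottleneck, vit] -> C_{d-1}
        self.bottleneck_fuse = Conv2d(ch[d - 1] + cfg.vit_dim, ch[d - 1], 1, rng)
        self.up_conv = ModuleList([Conv2d(ch[i + 1], ch[i], 3, rng) for i in range(d - 1)])
        # decoder fusion: [upsampled, plam(skip), vit] -> C_i
        self.fuse = ModuleList([Conv2d(2 * ch[i] + cfg.vit_dim, ch[i], 1, rng)
                                for i in range(d - 1)])
        self.dec = ModuleList([DoubleConv(ch[i], ch[i], rng) for i in range(d - 1)])
        self.se_up = ModuleList([
            SEBlock(ch[i], rng, cfg.se_reduction) if cfg.se_placement in ("up", "all") else Module()
            for i in range(d - 1)])
        self.head = Conv2d(ch[0], 1, 1, rng)

    def forward(self, images: Tensor, text: Tensor | None = None) -> Tensor:
        """images: (B,1,H,W) in [0,1]; text: (B,1,D_text) pooled embedding or None."""
        if images.ndim != 4 or images.shape[1] != 1:
            raise ValueError(f"expected (B,1,H,W) input, got {images.shape}")
        if tuple(images.shape[2:]) != tuple(self.cfg.input_size):
            raise ValueError(
                f"input size {images.shape[2:]} != configured {self.cfg.input_size}")
        d = self.cfg.depth
        feats: list[Tensor] = []
        x = images
        for i in range(d):
            x = self.enc[i](x)
            if self.cfg.se_placement in ("down", "all"):
                x = self.se_down[i](x)
            feats.append(x)
            if i < d - 1:
                x = F.max_pool2d(x, 2)

        vit_maps = self.vit(feats, text)  # per level, (B, D, g_i, g_i)
        up_vit = [F.upsample_nearest(m, PATCH) for m in vit_maps]

        x = self.bottleneck_fuse(F.concat([feats[d - 1], up_vit[d - 1]], axis=1))
        for i in range(d - 2, -1, -1):
            x = self.up_conv[i](F.upsample_nearest(x, 2))
            skip = self.plam[i](feats[i])
            x = self.fuse[i](F.concat([x, skip, up_vit[i]], axis=1))
            x = self.dec[i](x)
            if self.cfg.se_placement in ("up", "all"):
                x = self.se_up[i](x)
        return F.sigmoid(self.head(x))


def build_model(cfg: ModelConfig, seed: int = 0) -> SegmentationModel:
    return SegmentationModel(cfg, np.random.default_rng(seed))


def expected_se_params(cfg: ModelConfig) -> int:
    """Closed-form count of SE-block parameters implied by the placement."""
    ch = cfg.encoder_channels
    total = 0
    if cfg.se_placement in ("down", "all"):
        total += sum(se_param_count(c, cfg.se_reduction) for c in ch)
    if cfg.se_placement in ("up", "all"):
        total += sum(se_param_count(c, cfg.se_reduction) for c in ch[:-1])
    return total


def expected_gate_params(cfg: ModelConfig) -> int:
    """Closed-form count of residual-gate parameters in the ViT branch."""
    if not cfg.gating_enabled:
        return 0
    n_layers = cfg.vit_depth * (2 * cfg.depth - 1)  # down levels + up levels
    return n_layers * gate_param_count(cfg.vit_dim, cfg.gate_granularity)
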