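"""U-shaped transformer branch with gated residual connections.

Each layer replaces the plain residual ``x + Attn(x)`` with
``x + Gate(x) * Attn(x)`` (and likewise for the feed-forward sub-layer),
where the gate is a per-token sigmoid of a learned affine map of the layer
input.  Gate weights start at zero and the bias at zero, so training begins
with every gate at 0.5 — midway between an identity layer and a standard
residual layer.

Layout decisions (committed): pre-normalization (LayerNorm before each
sub-layer), gates computed from the raw (un-normalized) sub-layer input,
and scalar-per-token gates by default (``granularity=1``); per-feature
gates are available with ``granularity=D``.

The branch itself is a token-space U: image tokens are formed from the CNN
encoder's level-matched feature maps by a learned patch projection, a pooled
text embedding is added to every entry-level token after a bias-free linear
projection, tokens are merged going down and expanded coming up, and the
per-level outputs are reshaped back to feature-map grids for the CNN
decoder.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Conv2d, LayerNorm, Linear, Module, ModuleList, Parameter, Tensor
from .autodiff import functional as F

__all__ = [
    "GateParams",
    "gate_signal",
    "GatedTransformerLayer",
    "gated_layer",
    "VitBranch",
    "gate_param_count",
]

PATCH = 4  # patch edge for token projection at every level


@dataclass
class GateParams:
    """Affine gate maps for the two sub-layers of one transformer layer."""

    attn_weight: np.ndarray  # (D, g)
    attn_bias: np.ndarray    # (g,)
    mlp_weight: np.ndarray   # (D, g)
    mlp_bias: np.ndarray     # (g,)

    def __post_init__(self):
        for name in ("attn_weight", "attn_bias", "mlp_weight", "mlp_bias"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        d, g = self.attn_weight.shape
        if self.mlp_weight.shape != (d, g):
            raise ValueError("attn/mlp gate shapes disagree")
        if self.attn_bias.shape != (g,) or self.mlp_bias.shape != (g,):
            raise ValueError("gate bias shape mismatch")
        if g not in (1, d):
            raise ValueError(f"gate granularity must be 1 or {d}, got {g}")

    @classmethod
    def zeros(cls, dim: int, granularity: int = 1) -> "GateParams":
        return cls(np.zeros((dim, granularity)), np.zeros(granularity),
                   np.zeros((dim, granularity)), np.zeros(granularity))


def gate_signal(x: np.ndarray, g: GateParams, which: str) -> np.ndarray:
    """Per-token gate values sigmoid(x @ W + b), each strictly in (0,1)."""
    x = np.asarray(x, dtype=float)
    if which == "attn":
        w, b = g.attn_weight, g.attn_bias
    elif which == "mlp":
        w, b = g.mlp_weight, g.mlp_bias
    else:
        raise ValueError(f"which must be 'attn' or 'mlp', got {which!r}")
    if x.ndim < 1 or x.shape[-1] != w.shape[0]:
        raise ValueError(f"token dim {x.shape} does not match gate dim {w.shape[0]}")
    return 1.0 / (1.0 + np.exp(-(x @ w + b)))


def gate_param_count(dim: int, granularity: int = 1) -> int:
    """Learnable scalars in the two gates of one gated layer."""
    return 2 * (dim * granularity + granularity)


class MultiHeadAttention(Module):
    def __init__(self, dim: int, heads: int, rng: np.random.Generator):
        super().__init__()
        if dim % heads:
            raise ValueError(f"heads ({heads}) must divide dim ({dim})")
        self.dim, self.heads = dim, heads
        self.head_dim = dim // heads
        self.wq = Linear(dim, dim, rng)
        self.wk = Linear(dim, dim, rng)
        self.wv = Linear(dim, dim, rng)
        self.wo = Linear(dim, dim, rng)
        self.last_attention: np.ndarray | None = None  # (B,h,N,N), diagnostics

    def forward(self, x: Tensor) -> Tensor:
        b, n, d = x.shape
        h, hd = self.heads, self.head_dim

        def split(t: Tensor) -> Tensor:  # (B,N,D) -> (B,h,N,hd)
            return t.reshape(b, n, h, hd).transpose(0, 2, 1, 3)

        q, k, v = split(self.wq(x)), split(self.wk(x)), split(self.wv(x))
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(hd))
        attn = F.softmax(scores, axis=-1)
        self.last_attention = attn.data
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(b, n, d)
        return self.wo(out)


class FeedForward(Module):
    def __init__(self, dim: int, rng: np.random.Generator, expansion: int = 4):
        super().__init__()
        self.fc1 = Linear(dim, expansion * dim, rng)
        self.fc2 = Linear(expansion * dim, dim, rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.fc2(F.relu(self.fc1(x)))


class GatedTransformerLayer(Module):
    """One pre-norm transformer layer, optionally with gated residuals."""

    def __init__(self, dim: int, heads: int, rng: np.random.Generator,
                 gated: bool = True, granularity: int = 1):
        super().__init__()
        if granularity not in (1, dim):
            raise ValueError(f"granularity must be 1 or {dim}")
        self.dim, self.gated, self.granularity = dim, gated, granularity
        self.norm1 = LayerNorm(dim)
        self.norm2 = LayerNorm(dim)
        self.attn = MultiHeadAttention(dim, heads, rng)
        self.mlp = FeedForward(dim, rng)
        if gated:
            # zero weights + zero bias => every gate starts at 0.5
            self.gate_attn_w = Parameter(np.zeros((dim, granularity)))
            self.gate_attn_b = Parameter(np.zeros(granularity))
            self.gate_mlp_w = Parameter(np.zeros((dim, granularity)))
            self.gate_mlp_b = Parameter(np.zeros(granularity))

    def _gate(self, x: Tensor, w: Parameter, b: Parameter) -> Tensor:
        return F.sigmoid(x @ w + b)

    def forward(self, x: Tensor) -> Tensor:
        a = self.attn(self.norm1(x))
        if self.gated:
            a = a * self._gate(x, self.gate_attn_w, self.gate_attn_b)
        y1 = a + x
        m = self.mlp(self.norm2(y1))
        if self.gated:
            m = m * self._gate(y1, self.gate_mlp_w, self.gate_mlp_b)
        return m + y1


def gated_layer(x: np.ndarray, layer: GatedTransformerLayer) -> np.ndarray:
    """Apply one layer to an un-batched (N, D) token array."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[1] != layer.dim:
        raise ValueError(f"expected (N, {layer.dim}) tokens, got {x.shape}")
    return layer(Tensor(x[None])).data[0]


def _tokens_to_grid(t: Tensor, edge: int) -> Tensor:
    b, n, d = t.shape
    return t.transpose(0, 2, 1).reshape(b, d, edge, edge)


def _grid_to_tokens(m: Tensor) -> Tensor:
    b, d, h, w = m.shape
    return m.reshape(b, d, h * w).transpose(0, 2, 1)


class VitBranch(Module):
    """Token-space U fed from CNN encoder features and a text embedding.

    Parameters
    ----------
    enc_channels : channel count of each encoder level (index 0 = finest).
    dim : token embedding dimension D.
    heads : attention heads per layer.
    layers_per_level : gated layers applied at each level on each of the
        down and up paths.
    text_dim : dimensionality of the pooled text embedding.
    gated : disable to recover plain residual transformer layers.
    """

    def __init__(self, enc_channels: list[int], grid_edges: list[int], dim: int,
                 heads: int, rng: np.random.Generator, text_dim: int = 768,
                 gated: bool = True, granularity: int = 1, layers_per_level: int = 1):
        super().__init__()
        self.levels = len(enc_channels)
        self.dim = dim
        self.grid_edges = list(grid_edges)
        self.proj = ModuleList([Conv2d(c, dim, 1, rng) for c in enc_channels])
        self.text_proj = Linear(text_dim, dim, rng, bias=False)
        self.pos = ModuleList()
        for e in grid_edges:
            holder = Module()
            holder.emb = Parameter(np.zeros((e * e, dim)))
            self.pos.append(holder)
        mk = lambda: ModuleList([
            GatedTransformerLayer(dim, heads, rng, gated=gated, granularity=granularity)
            for _ in range(layers_per_level)
        ])
        self.down_layers = ModuleList([mk() for _ in range(self.levels)])
        self.up_layers = ModuleList([mk() for _ in range(self.levels - 1)])
        self.merge_down = ModuleList([Linear(dim, dim, rng) for _ in range(self.levels - 1)])
        self.expand_up = ModuleList([Linear(dim, dim, rng) for _ in range(self.levels - 1)])

    def forward(self, enc_feats: list[Tensor], text: Tensor | None) -> list[Tensor]:
        """Return one (B, D, g_i, g_i) map per level (index 0 = finest)."""
        if len(enc_feats) != self.levels:
            raise ValueError(f"expected {self.levels} encoder maps, got {len(enc_feats)}")
        down: list[Tensor] = []
        t: Tensor | None = None
        for i, feat in enumerate(enc_feats):
            edge = self.grid_edges[i]
            patched = F.avg_pool2d(self.proj[i](feat), feat.shape[2] // edge)
            tok = _grid_to_tokens(patched) + self.pos[i].emb
            if i == 0 and text is not None:
                if text.shape[-1] != self.text_proj.in_dim:
                    raise ValueError(
                        f"text embedding dim {text.shape[-1]} != {self.text_proj.in_dim}")
                if text.ndim == 3:        # (B, N_text, D_text): one caption per image
                    add = self.text_proj(text.mean(axis=1)).reshape(text.shape[0], 1, self.dim)
                elif text.ndim == 2:      # (N_text, D_text): shared caption
                    add = self.text_proj(text.mean(axis=0).reshape(1, -1)).reshape(1, 1, self.dim)
                else:                     # (D_text,): pre-pooled
                    add = self.text_proj(text.reshape(1, -1)).reshape(1, 1, self.dim)
                tok = tok + add
            if i > 0:
                carried = _grid_to_tokens(F.avg_pool2d(_tokens_to_grid(t, self.grid_edges[i - 1]), 2))
                tok = tok + self.merge_down[i - 1](carried)
            for layer in self.down_layers[i]:
                tok = layer(tok)
            down.append(tok)
            t = tok
        up = down[-1]
        outputs = [up]
        for i in range(self.levels - 2, -1, -1):
            expanded = _grid_to_tokens(
                F.upsample_nearest(_tokens_to_grid(self.expand_up[i](up), self.grid_edges[i + 1]), 2))
            up = expanded + down[i]
            for layer in self.up_layers[i]:
                up = layer(up)
            outputs.append(up)
        outputs.reverse()  # index 0 = finest level
        return [_tokens_to_grid(o, self.grid_edges[i]) for i, o in enumerate(outputs)]
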