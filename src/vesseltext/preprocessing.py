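"""Deterministic image preprocessing chain.

Order is fixed: grayscale conversion → intensity normalization → CLAHE →
gamma correction.  All operations preserve image dimensions and are free of
randomness.  CLAHE is implemented directly (tile-wise clipped histogram
equalization with bilinear interpolation between tile mappings) so that its
clip-limit/tile-grid semantics are exactly the ones documented here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = [
    "PreprocessConfig",
    "to_grayscale",
    "normalize",
    "apply_clahe",
    "gamma_correct",
    "preprocess",
    "load_image",
]

logger = logging.getLogger(__name__)

# ITU-R BT.601 luminance weights
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass
class PreprocessConfig:
    clahe_clip_limit: float = 2.0
    clahe_tile_grid: tuple[int, int] = (8, 8)
    gamma: float = 1.2
    normalize_mode: str = "min_max"

    def __post_init__(self):
        if self.clahe_clip_limit <= 0:
            raise ValueError("clahe_clip_limit must be positive")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.normalize_mode not in ("min_max", "z_score"):
            raise ValueError(f"unknown normalize mode {self.normalize_mode!r}")


def load_image(path: str | Path) -> np.ndarray:
    """Read PNG/TIFF/JPEG into a float array (H,W) or (H,W,3)."""
    img = Image.open(path)
    if img.mode not in ("L", "RGB"):
        img = img.convert("RGB")
    return np.asarray(img, dtype=float)


def to_grayscale(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img, dtype=float)
    if img.ndim == 2:
        return img.copy()
    if img.ndim == 3 and img.shape[2] in (3, 4):
        return img[..., :3] @ _LUMA
    raise ValueError(f"expected (H,W) or (H,W,3) image, got shape {img.shape}")


def normalize(img: np.ndarray, mode: str = "min_max") -> np.ndarray:
    img = np.asarray(img, dtype=float)
    if mode == "min_max":
        lo, hi = img.min(), img.max()
        if hi == lo:
            logger.warning("constant image in min_max normalization; returning zeros")
            return np.zeros_like(img)
        return (img - lo) / (hi - lo)
    if mode == "z_score":
        sd = img.std()
        if sd == 0:
            logger.warning("constant image in z_score normalization; returning zeros")
            return np.zeros_like(img)
        return (img - img.mean()) / sd
    raise ValueError(f"unknown normalize mode {mode!r}")


def _tile_mapping(tile: np.ndarray, nbins: int, clip_limit: float) -> np.ndarray:
    """Clipped-equalization lookup table (bin index -> [0,1]) for one tile."""
    hist = np.bincount(tile.ravel(), minlength=nbins).astype(float)
    clip = max(clip_limit * tile.size / nbins, 1.0)
    excess = np.clip(hist - clip, 0.0, None).sum()
    hist = np.minimum(hist, clip) + excess / nbins
    cdf = hist.cumsum()
    return cdf / cdf[-1]


def apply_clahe(img: np.ndarray, clip_limit: float = 2.0,
                tile_grid: tuple[int, int] = (8, 8), nbins: int = 256) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization on a [0,1] image.

    Tile histograms are clipped at ``clip_limit`` times the uniform level and
    the excess redistributed evenly; pixel values are remapped by bilinear
    interpolation between the equalization curves of the four nearest tiles.
    """
    img = np.asarray(img, dtype=float)
    if img.ndim != 2:
        raise ValueError("CLAHE expects a grayscale image")
    if clip_limit <= 0:
        raise ValueError("clip_limit must be positive")
    h, w = img.shape
    tr, tc = tile_grid
    tr, tc = min(tr, h), min(tc, w)

    bins = np.clip((img * (nbins - 1)).round().astype(int), 0, nbins - 1)
    row_edges = np.linspace(0, h, tr + 1).astype(int)
    col_edges = np.linspace(0, w, tc + 1).astype(int)
    maps = np.empty((tr, tc, nbins))
    for i in range(tr):
        for j in range(tc):
            tile = bins[row_edges[i]:row_edges[i + 1], col_edges[j]:col_edges[j + 1]]
            maps[i, j] = _tile_mapping(tile, nbins, clip_limit)

    centers_r = (row_edges[:-1] + row_edges[1:]) / 2.0
    centers_c = (col_edges[:-1] + col_edges[1:]) / 2.0
    rows = np.arange(h) + 0.5
    cols = np.arange(w) + 0.5

    r1 = np.clip(np.searchsorted(centers_r, rows), 0, tr - 1)
    r0 = np.clip(r1 - 1, 0, tr - 1)
    c1 = np.clip(np.searchsorted(centers_c, cols), 0, tc - 1)
    c0 = np.clip(c1 - 1, 0, tc - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        wr = np.where(r1 > r0, (rows - centers_r[r0]) / (centers_r[r1] - centers_r[r0]), 0.0)
        wc = np.where(c1 > c0, (cols - centers_c[c0]) / (centers_c[c1] - centers_c[c0]), 0.0)
    wr = np.clip(wr, 0.0, 1.0)[:, None]
    wc = np.clip(wc, 0.0, 1.0)[None, :]

    def lookup(ri, ci):
        return maps[ri[:, None], ci[None, :], bins]

    out = ((1 - wr) * (1 - wc) * lookup(r0, c0)
           + (1 - wr) * wc * lookup(r0, c1)
           + wr * (1 - wc) * lookup(r1, c0)
           + wr * wc * lookup(r1, c1))
    return np.clip(out, 0.0, 1.0)  # guard float round-off at the top end


def gamma_correct(img: np.ndarray, gamma: float) -> np.ndarray:
    """Power-law mapping out = in**gamma on [0,1] intensities."""
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    img = np.asarray(img, dtype=float)
    if img.min() < 0 or img.max() > 1:
        raise ValueError("gamma correction expects intensities in [0,1]")
    return img**gamma


def preprocess(img: np.ndarray, cfg: PreprocessConfig | None = None) -> np.ndarray:
    """Full chain: grayscale → normalize → CLAHE → gamma. Output in [0,1]."""
    cfg = cfg or PreprocessConfig()
    g = to_grayscale(img)
    g = normalize(g, cfg.normalize_mode)
    if cfg.normalize_mode == "z_score":  # CLAHE/gamma need [0,1]
        g = normalize(g, "min_max")
    g = apply_clahe(g, cfg.clahe_clip_limit, cfg.clahe_tile_grid)
    return gamma_correct(g, cfg.gamma)
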