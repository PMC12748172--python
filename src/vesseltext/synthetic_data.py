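"""Procedural generator of vessel-like images, masks and captions.

Two modalities are emulated: ``cf`` — a few thick trunks radiating inward
with a bright disc blob, coarse-vessel look; ``octa`` — many fine trunks
forming a dense mesh with a vessel-free central disc (the avascular zone).
Trees grow by recursive binary branching from peripheral seed points toward
the image center, with segment width shrinking by ``width_decay`` each
generation.  The caption is generated from descriptors *measured on the
rendered mask*, so label and mask are consistent by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter

from .text_pipeline import LabelTable, TextLabel, generate_caption, write_label_table

__all__ = ["SynthConfig", "Segment", "SyntheticSample", "grow_vessel_tree",
           "rasterize_segments", "generate_sample", "generate_dataset"]


@dataclass
class Segment:
    """One widened polyline piece: endpoints in (row, col) pixels."""

    p0: tuple[float, float]
    p1: tuple[float, float]
    width: float


@dataclass
class SynthConfig:
    modality: str = "octa"
    size: tuple[int, int] = (64, 64)
    n_trees: int = 14
    branch_depth: int = 3
    width_decay: float = 0.8
    initial_width: float = 1.6
    segment_length_frac: float = 0.16   # of min(H, W), per generation
    branch_angle: float = 0.55          # radians, half-spread at a fork
    noise_sd: float = 0.08
    blur_sigma: float = 0.7
    vessel_contrast: float = 0.7
    fovea_radius_frac: float = 0.2
    abnormal_prob: float = 0.0
    density_cutpoints: tuple[float, float] = (0.05, 0.15)
    seed: int = 0

    def __post_init__(self):
        if self.modality not in ("cf", "octa"):
            raise ValueError(f"unknown modality {self.modality!r}")
        h, w = self.size
        if h < 32 or w < 32:
            raise ValueError("image size must be at least 32x32")
        if not 0 < self.width_decay < 1:
            raise ValueError("width_decay must be in (0,1)")
        if self.noise_sd < 0 or self.blur_sigma < 0:
            raise ValueError("noise_sd and blur_sigma must be nonnegative")

    @classmethod
    def cf(cls, **kw) -> "SynthConfig":
        """Coarse-vessel preset: few thick radial trunks, bright disc blob."""
        defaults = dict(modality="cf", n_trees=5, branch_depth=3, initial_width=2.6,
                        width_decay=0.75, fovea_radius_frac=0.0, segment_length_frac=0.2)
        defaults.update(kw)
        return cls(**defaults)

    @classmethod
    def octa(cls, **kw) -> "SynthConfig":
        """Fine-mesh preset with a central avascular disc."""
        defaults = dict(modality="octa", n_trees=14, branch_depth=3, initial_width=1.6,
                        width_decay=0.8, fovea_radius_frac=0.2)
        defaults.update(kw)
        return cls(**defaults)


@dataclass
class SyntheticSample:
    image: np.ndarray   # float (H,W) in [0,1]
    mask: np.ndarray    # uint8 (H,W) in {0,1}
    label: TextLabel
    config: SynthConfig = field(repr=False, default=None)


def _fovea_radius(cfg: SynthConfig) -> float:
    return cfg.fovea_radius_frac * min(cfg.size) / 2.0


def grow_vessel_tree(cfg: SynthConfig, rng: np.random.Generator) -> list[Segment]:
    """Grow all trees for one image; returns widened polyline segments."""
    h, w = cfg.size
    center = np.array([h / 2.0, w / 2.0])
    seg_len = cfg.segment_length_frac * min(h, w)
    fovea_r = _fovea_radius(cfg) if cfg.modality == "octa" else 0.0
    segments: list[Segment] = []

    def blocked(point: np.ndarray, width: float) -> bool:
        return fovea_r > 0 and np.linalg.norm(point - center) < fovea_r + width / 2.0

    def grow(point: np.ndarray, angle: float, width: float, depth: int) -> None:
        step = seg_len * (0.85 + 0.3 * rng.random())
        nxt = point + step * np.array([np.sin(angle), np.cos(angle)])
        nxt = np.clip(nxt, 1.0, [h - 2.0, w - 2.0])
        if blocked(nxt, width):
            # shorten the step so the segment stops at the avascular boundary
            direction = nxt - point
            norm = np.linalg.norm(direction)
            if norm == 0:
                return
            lo, hi = 0.0, 1.0
            for _ in range(24):
                mid = (lo + hi) / 2.0
                if blocked(point + mid * direction, width):
                    hi = mid
                else:
                    lo = mid
            nxt = point + lo * direction
            if np.linalg.norm(nxt - point) > 1.0:
                segments.append(Segment(tuple(point), tuple(nxt), width))
            return
        segments.append(Segment(tuple(point), tuple(nxt), width))
        if depth <= 0:
            return
        spread = cfg.branch_angle * (0.7 + 0.6 * rng.random())
        for sign in (-1.0, 1.0):
            grow(nxt, angle + sign * spread * rng.uniform(0.5, 1.0),
                 width * cfg.width_decay, depth - 1)

    for _ in range(cfg.n_trees):
        side = rng.integers(4)
        u = rng.uniform(0.1, 0.9)
        if side == 0:
            start = np.array([1.0, u * (w - 2)])
        elif side == 1:
            start = np.array([h - 2.0, u * (w - 2)])
        elif side == 2:
            start = np.array([u * (h - 2), 1.0])
        else:
            start = np.array([u * (h - 2), w - 2.0])
        to_center = center - start
        angle = np.arctan2(to_center[0], to_center[1]) + rng.normal(0, 0.25)
        if blocked(start, cfg.initial_width):
            continue
        grow(start, angle, cfg.initial_width, cfg.branch_depth)
    return segments


def rasterize_segments(segments: list[Segment], size: tuple[int, int],
                       fovea_center: tuple[float, float] | None = None,
                       fovea_radius: float = 0.0) -> np.ndarray:
    """Render widened segments into a binary mask (distance-to-segment test)."""
    h, w = size
    mask = np.zeros((h, w), dtype=bool)
    for seg in segments:
        p0, p1 = np.array(seg.p0), np.array(seg.p1)
        r = seg.width / 2.0
        lo = np.maximum(np.floor(np.minimum(p0, p1) - r - 1).astype(int), 0)
        hi = np.minimum(np.ceil(np.maximum(p0, p1) + r + 1).astype(int), [h - 1, w - 1])
        if (hi < lo).any():
            continue
        yy, xx = np.mgrid[lo[0]:hi[0] + 1, lo[1]:hi[1] + 1]
        d = p1 - p0
        denom = float(d @ d)
        if denom == 0:
            dist = np.hypot(yy - p0[0], xx - p0[1])
        else:
            t = np.clip(((yy - p0[0]) * d[0] + (xx - p0[1]) * d[1]) / denom, 0.0, 1.0)
            dist = np.hypot(yy - (p0[0] + t * d[0]), xx - (p0[1] + t * d[1]))
        mask[lo[0]:hi[0] + 1, lo[1]:hi[1] + 1] |= dist <= max(r, 0.5)
    if fovea_radius > 0 and fovea_center is not None:
        yy, xx = np.mgrid[0:h, 0:w]
        mask[np.hypot(yy - fovea_center[0], xx - fovea_center[1]) < fovea_radius] = False
    return mask.astype(np.uint8)


def _density_class(fraction: float, cutpoints: tuple[float, float]) -> str:
    lo, hi = cutpoints
    if fraction < lo:
        return "sparse"
    if fraction < hi:
        return "moderate"
    return "dense"


_REGIONS = ["upper left", "upper right", "lower left", "lower right"]


def generate_sample(cfg: SynthConfig, image_id: str = "sample.png") -> SyntheticSample:
    rng = np.random.default_rng(cfg.seed)
    h, w = cfg.size
    center = (h / 2.0, w / 2.0)
    segments = grow_vessel_tree(cfg, rng)
    fovea_r = _fovea_radius(cfg) if cfg.modality == "octa" else 0.0
    mask = rasterize_segments(segments, cfg.size, center, fovea_r)

    vessel = mask.astype(float)
    if cfg.blur_sigma > 0:
        vessel = gaussian_filter(vessel, cfg.blur_sigma)
    img = cfg.vessel_contrast * vessel

    abnormal: list[str] = []
    if cfg.modality == "cf":
        # bright disc blob near the border, toward which trunks converge
        cy, cx = h * rng.uniform(0.3, 0.7), w * rng.uniform(0.08, 0.2)
        yy, xx = np.mgrid[0:h, 0:w]
        img += 0.35 * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * (0.08 * h) ** 2))
    if cfg.abnormal_prob > 0 and rng.random() < cfg.abnormal_prob:
        q = rng.integers(4)
        cy = h * (0.25 if q < 2 else 0.75)
        cx = w * (0.25 if q % 2 == 0 else 0.75)
        yy, xx = np.mgrid[0:h, 0:w]
        img += 0.3 * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * (0.06 * h) ** 2))
        abnormal.append(_REGIONS[q])
    if cfg.noise_sd > 0:
        img = img + rng.normal(0.0, cfg.noise_sd, size=(h, w))
    img = np.clip(img, 0.0, 1.0)

    fraction = mask.mean()
    density = _density_class(fraction, cfg.density_cutpoints)
    distribution = "radial" if cfg.modality == "cf" else "reticular"
    caption = generate_caption(density, distribution, abnormal)
    label = TextLabel(image_id=image_id, caption=caption, density_class=density,
                      distribution_class=distribution, abnormal_areas=abnormal)
    return SyntheticSample(image=img, mask=mask, label=label, config=cfg)


def _save_png(arr: np.ndarray, path: Path) -> None:
    Image.fromarray(np.clip(arr * 255.0, 0, 255).round().astype(np.uint8)).save(path)


def generate_dataset(cfg: SynthConfig, n_train: int, n_test: int,
                     out_dir: str | Path) -> dict:
    """Write images/, masks/, labels.csv and manifest.json; fully seeded."""
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)
    labels: list[TextLabel] = []
    splits = {"train": [], "test": []}
    for i in range(n_train + n_test):
        image_id = f"{cfg.modality}_{i:04d}.png"
        sample = generate_sample(replace(cfg, seed=cfg.seed + i), image_id=image_id)
        _save_png(sample.image, out_dir / "images" / image_id)
        _save_png(sample.mask.astype(float), out_dir / "masks" / image_id)
        labels.append(sample.label)
        splits["train" if i < n_train else "test"].append(image_id)
    write_label_table(LabelTable(labels), out_dir / "labels.csv")
    manifest = {"modality": cfg.modality, "size": list(cfg.size), "seed": cfg.seed,
                "n_train": n_train, "n_test": n_test, "splits": splits,
                "labels": "labels.csv"}
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
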