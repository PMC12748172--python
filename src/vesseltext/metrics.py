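"""Pixel-level segmentation metrics: F1, accuracy, sensitivity, specificity.

Vessel pixels are the positive class.  Dataset-level metrics pool the
confusion counts over images (micro-average); a per-image macro-average is
also reported for transparency.  Ratios with a zero denominator are reported
as ``None`` and flagged, never silently coerced to 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["ConfusionCounts", "MetricsReport", "binarize", "confusion",
           "compute_metrics", "aggregate", "write_report"]


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        for name in ("tp", "tn", "fp", "fn"):
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise ValueError(f"{name} must be a nonnegative integer, got {v}")
            setattr(self, name, int(v))

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.tn + other.tn,
                               self.fp + other.fp, self.fn + other.fn)


@dataclass
class MetricsReport:
    f1: float | None
    acc: float | None
    se: float | None
    sp: float | None
    undefined: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {"f1": self.f1, "acc": self.acc, "se": self.se, "sp": self.sp,
                "undefined": list(self.undefined)}


def binarize(prob_map: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Threshold a probability map: pixel = 1 iff prob >= threshold."""
    prob_map = np.asarray(prob_map, dtype=float)
    if prob_map.ndim != 2:
        raise ValueError("probability map must be rank-2")
    if prob_map.min() < 0 or prob_map.max() > 1:
        raise ValueError("probabilities must lie in [0,1]")
    return (prob_map >= threshold).astype(np.uint8)


def _check_mask(m: np.ndarray, name: str) -> np.ndarray:
    m = np.asarray(m)
    if m.ndim != 2:
        raise ValueError(f"{name} must be rank-2")
    if not np.isin(m, (0, 1)).all():
        raise ValueError(f"{name} must be strictly binary")
    return m.astype(bool)


def confusion(pred: np.ndarray, gt: np.ndarray) -> ConfusionCounts:
    """Exhaustive pixel partition into TP/TN/FP/FN (vessel = positive)."""
    pred = _check_mask(pred, "pred")
    gt = _check_mask(gt, "gt")
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs gt {gt.shape}")
    tp = int(np.count_nonzero(pred & gt))
    tn = int(np.count_nonzero(~pred & ~gt))
    fp = int(np.count_nonzero(pred & ~gt))
    fn = int(np.count_nonzero(~pred & gt))
    return ConfusionCounts(tp, tn, fp, fn)


def compute_metrics(c: ConfusionCounts) -> MetricsReport:
    """F1 = 2TP/(2TP+FP+FN); Acc = (TP+TN)/total; Se = TP/(TP+FN); Sp = TN/(TN+FP)."""
    if c.total == 0:
        raise ValueError("confusion counts are all zero")
    undefined: list[str] = []

    def ratio(num: int, den: int, name: str) -> float | None:
        if den == 0:
            undefined.append(name)
            return None
        return num / den

    f1 = ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn, "f1")
    acc = (c.tp + c.tn) / c.total
    se = ratio(c.tp, c.tp + c.fn, "se")
    sp = ratio(c.tn, c.tn + c.fp, "sp")
    return MetricsReport(f1=f1, acc=acc, se=se, sp=sp, undefined=undefined)


def aggregate(counts: list[ConfusionCounts]) -> dict:
    """Pooled (micro) report plus per-image macro means of defined values."""
    if not counts:
        raise ValueError("no confusion counts to aggregate")
    pooled = counts[0]
    for c in counts[1:]:
        pooled = pooled + c
    micro = compute_metrics(pooled)
    per_image = [compute_metrics(c) for c in counts]
    macro = {}
    for key in ("f1", "acc", "se", "sp"):
        vals = [getattr(r, key) for r in per_image if getattr(r, key) is not None]
        macro[key] = float(np.mean(vals)) if vals else None
    return {"micro": micro.as_dict(), "macro": macro,
            "per_image": [r.as_dict() for r in per_image]}


def write_report(report: dict, out_dir: str | Path, stem: str = "metrics") -> None:
    """Write a report dict as JSON plus a flat CSV of the micro/macro rows."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / f"{stem}.json").write_text(json.dumps(report, indent=2) + "\n")
    lines = ["scope,f1,acc,se,sp"]
    for scope in ("micro", "macro"):
        row = report[scope]
        lines.append(scope + "," + ",".join(
            "" if row[k] is None else f"{row[k]:.6f}" for k in ("f1", "acc", "se", "sp")))
    (out_dir / f"{stem}.csv").write_text("\n".join(lines) + "\n")
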