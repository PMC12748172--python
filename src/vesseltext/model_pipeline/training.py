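"""Training, evaluation, checkpointing and the SE-placement ablation runner."""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from ..autodiff import Adam, SGD, Tensor
from ..autodiff import functional as F
from ..metrics import aggregate, binarize, confusion
from ..preprocessing import PreprocessConfig, load_image, preprocess
from ..text_pipeline import embed_text, read_label_table
from .config import ModelConfig, TrainConfig
from .model import SegmentationModel, build_model

logger = logging.getLogger(__name__)

__all__ = ["SegSample", "SegDataset", "load_dataset", "bce_dice_loss", "Checkpoint",
           "train", "evaluate", "predict", "run_ablation"]

_EPS = 1e-7


@dataclass
class SegSample:
    image_id: str
    image: np.ndarray          # (H,W) float in [0,1]
    mask: np.ndarray           # (H,W) uint8 {0,1}
    text: np.ndarray           # (D_text,) pooled caption embedding


@dataclass
class SegDataset:
    samples: list[SegSample]

    def __post_init__(self):
        if not self.samples:
            raise ValueError("dataset is empty")

    def __len__(self):
        return len(self.samples)

    def __iter__(self):
        return iter(self.samples)


def pooled_text_embedding(caption: str, cfg: ModelConfig, seed: int = 0) -> np.ndarray:
    """Mean stub/pretrained token embedding; empty caption → zero vector."""
    if not caption:
        return np.zeros(cfg.text_dim)
    emb = embed_text(caption, embedder=cfg.text_embedder,
                     max_tokens=cfg.text_max_tokens, seed=seed, dim=cfg.text_dim)
    return emb.mean(axis=0)


def load_dataset(data_dir: str | Path, split: str, cfg: ModelConfig,
                 apply_preprocessing: bool = True,
                 preprocess_cfg: PreprocessConfig | None = None,
                 text_seed: int = 0, drop_captions: bool = False) -> SegDataset:
    """Build a dataset from a generate_dataset() directory and its manifest."""
    data_dir = Path(data_dir)
    manifest = json.loads((data_dir / "manifest.json").read_text())
    labels = read_label_table(data_dir / manifest.get("labels", "labels.csv"))
    samples = []
    for image_id in manifest["splits"][split]:
        img = load_image(data_dir / "images" / image_id)
        if apply_preprocessing:
            img = preprocess(img, preprocess_cfg)
        else:
            img = np.asarray(img, dtype=float) / 255.0
        mask = (load_image(data_dir / "masks" / image_id) > 127).astype(np.uint8)
        caption = "" if drop_captions else labels[image_id].caption
        samples.append(SegSample(image_id, img, mask,
                                 pooled_text_embedding(caption, cfg, text_seed)))
    return SegDataset(samples)


def bce_dice_loss(probs: Tensor, target: np.ndarray) -> Tensor:
    """Equally weighted binary cross-entropy + soft Dice on probabilities."""
    t = Tensor(np.asarray(target, dtype=float))
    bce_terms = t * F.log(probs + _EPS) + (1.0 - t) * F.log(1.0 - probs + _EPS)
    bce = -bce_terms.mean()
    inter = (probs * t).sum()
    dice = 1.0 - (2.0 * inter + 1.0) / (probs.sum() + t.sum() + 1.0)
    return bce + dice


@dataclass
class Checkpoint:
    state: dict[str, np.ndarray]
    model_config: ModelConfig
    train_config: TrainConfig
    epoch: int
    history: list[dict] = field(default_factory=list)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        meta = json.dumps({"model_config": self.model_config.as_dict(),
                           "train_config": self.train_config.as_dict(),
                           "epoch": self.epoch, "history": self.history})
        with open(path, "wb") as fh:  # explicit handle: keep the exact filename
            np.savez(fh, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
                     **{f"param/{k}": v for k, v in self.state.items()})

    @classmethod
    def load(cls, path: str | Path) -> "Checkpoint":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            state = {k[len("param/"):]: data[k] for k in data.files if k.startswith("param/")}
        return cls(state=state,
                   model_config=ModelConfig.from_dict(meta["model_config"]),
                   train_config=TrainConfig.from_dict(meta["train_config"]),
                   epoch=meta["epoch"], history=meta["history"])

    def build(self) -> SegmentationModel:
        model = build_model(self.model_config)
        model.load_state_dict(self.state)
        return model


def _batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for i in range(0, n, batch_size):
        yield order[i:i + batch_size]


def _stack_batch(samples: list[SegSample], idx) -> tuple[Tensor, Tensor, np.ndarray]:
    imgs = np.stack([samples[i].image for i in idx])[:, None]          # (B,1,H,W)
    masks = np.stack([samples[i].mask for i in idx]).astype(float)[:, None]
    text = np.stack([samples[i].text for i in idx])[:, None]           # (B,1,Dt)
    return Tensor(imgs), Tensor(text), masks


def train(model: SegmentationModel, dataset: SegDataset, tcfg: TrainConfig,
          checkpoint_path: str | Path | None = None,
          log_path: str | Path | None = None) -> Checkpoint:
    """Optimize the model; returns the checkpoint of the best epoch loss."""
    samples = dataset.samples
    params = model.parameters()
    opt = (Adam(params, lr=tcfg.learning_rate) if tcfg.optimizer == "adam"
           else SGD(params, lr=tcfg.learning_rate))
    shuffle_rng = np.random.default_rng(tcfg.seed)
    history: list[dict] = []
    best_loss = np.inf
    best = Checkpoint(model.state_dict(), model.cfg, tcfg, epoch=0)
    log_fh = open(log_path, "a") if log_path else None
    try:
        for epoch in range(1, tcfg.epochs + 1):
            t0 = time.perf_counter()
            losses = []
            for idx in _batches(len(samples), tcfg.batch_size, shuffle_rng):
                imgs, text, masks = _stack_batch(samples, idx)
                probs = model(imgs, text)
                loss = bce_dice_loss(probs, masks)
                if not np.isfinite(loss.data):
                    raise RuntimeError(
                        f"non-finite loss {loss.data} at epoch {epoch}; "
                        "aborting (check learning rate / inputs)")
                opt.zero_grad()
                loss.backward()
                opt.step()
                losses.append(float(loss.data))
            epoch_loss = float(np.mean(losses))
            record = {"epoch": epoch, "loss": epoch_loss, "seed": tcfg.seed,
                      "time_s": round(time.perf_counter() - t0, 3)}
            history.append(record)
            if log_fh:
                log_fh.write(json.dumps(record) + "\n")
                log_fh.flush()
            logger.info("epoch %d loss %.5f", epoch, epoch_loss)
            if epoch_loss < best_loss:
                best_loss = epoch_loss
                best = Checkpoint(model.state_dict(), model.cfg, tcfg,
                                  epoch=epoch, history=list(history))
                if checkpoint_path:
                    best.save(checkpoint_path)
    finally:
        if log_fh:
            log_fh.close()
    best.history = list(history)
    if checkpoint_path:
        best.save(checkpoint_path)
    return best


def predict(model: SegmentationModel, dataset: SegDataset) -> dict[str, np.ndarray]:
    """Per-image probability maps, computed one image at a time."""
    out = {}
    for s in dataset:
        probs = model(Tensor(s.image[None, None]), Tensor(s.text[None, None]))
        out[s.image_id] = probs.data[0, 0]
    return out


def evaluate(checkpoint: Checkpoint | SegmentationModel, dataset: SegDataset,
             threshold: float = 0.5) -> dict:
    """binarize → confusion → metrics, pooled (micro) and per-image (macro)."""
    model = checkpoint.build() if isinstance(checkpoint, Checkpoint) else checkpoint
    probs = predict(model, dataset)
    counts = [confusion(binarize(probs[s.image_id], threshold), s.mask) for s in dataset]
    report = aggregate(counts)
    report["per_image_ids"] = [s.image_id for s in dataset]
    return report


def run_ablation(placements: list[str], gating: list[bool], base_model_cfg: ModelConfig,
                 tcfg: TrainConfig, train_set: SegDataset, test_set: SegDataset,
                 out_dir: str | Path | None = None) -> list[dict]:
    """Train each (placement, gating) arm with a shared seed; return a table.

    Every arm sees the identical dataset and the identical shuffling stream
    (fresh RNG from the shared seed), so rows are directly comparable.
    """
    arms = [(p, g) for p in placements for g in gating]
    if len(arms) < 2:
        raise ValueError("ablation needs at least two configurations")
    rows = []
    for placement, gated in arms:
        mcfg = replace(base_model_cfg, se_placement=placement, gating_enabled=gated)
        model = build_model(mcfg, seed=tcfg.seed)
        ckpt = train(model, train_set, tcfg)
        report = evaluate(ckpt, test_set)
        row = {"model": f"se={placement},gating={'on' if gated else 'off'}",
               "se_placement": placement, "gating": gated,
               **{k: report["micro"][k] for k in ("f1", "acc", "se", "sp")}}
        rows.append(row)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "ablation.json").write_text(json.dumps(rows, indent=2) + "\n")
        header = "model,f1,acc,se,sp"
        lines = [header] + [
            f"{r['model']}," + ",".join(
                "" if r[k] is None else f"{r[k]:.6f}" for k in ("f1", "acc", "se", "sp"))
            for r in rows]
        (out_dir / "ablation.csv").write_text("\n".join(lines) + "\n")
    return rows
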