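"""Text-label construction, storage and embedding.

Captions are assembled from a small template grammar over three descriptor
axes — vessel density, vessel distribution, and abnormal areas — and stored
in a per-image label table (CSV canonically, XLSX supported).  Embedding is
provided by a fully offline deterministic stub (seeded hash per token) so the
pipeline never requires pretrained weights; a pretrained transformer encoder
can be plugged in when available.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import BackendUnavailableError, FormatError, ValidationError

__all__ = [
    "DENSITY_CLASSES",
    "DISTRIBUTION_CLASSES",
    "TextLabel",
    "LabelTable",
    "generate_caption",
    "read_label_table",
    "write_label_table",
    "embed_text",
]

DENSITY_CLASSES = ("sparse", "moderate", "dense")
DISTRIBUTION_CLASSES = ("radial", "reticular", "mixed")

_COLUMNS = ["image_id", "caption", "density_class", "distribution_class", "abnormal_areas"]
_AREA_SEP = ";"


def _default_templates() -> dict:
    with resources.files("vesseltext.data").joinpath("captions.yaml").open() as fh:
        return yaml.safe_load(fh)


@dataclass
class TextLabel:
    image_id: str
    caption: str
    density_class: str
    distribution_class: str
    abnormal_areas: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.image_id:
            raise ValidationError("image_id must be non-empty")
        if not self.caption:
            raise ValidationError("caption must be non-empty")
        if self.density_class not in DENSITY_CLASSES:
            raise ValidationError(f"unknown density class {self.density_class!r}")
        if self.distribution_class not in DISTRIBUTION_CLASSES:
            raise ValidationError(f"unknown distribution class {self.distribution_class!r}")


@dataclass
class LabelTable:
    rows: list[TextLabel]

    def __post_init__(self):
        ids = [r.image_id for r in self.rows]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ValidationError(f"duplicate image ids: {sorted(dupes)}")
        self._index = {r.image_id: r for r in self.rows}

    def __len__(self):
        return len(self.rows)

    def __getitem__(self, image_id: str) -> TextLabel:
        return self._index[image_id]

    def __contains__(self, image_id: str) -> bool:
        return image_id in self._index

    def image_ids(self) -> list[str]:
        return [r.image_id for r in self.rows]


def generate_caption(density_class: str, distribution_class: str,
                     abnormal_areas: list[str] | None = None,
                     templates: dict | None = None) -> str:
    """Build a caption mentioning each descriptor axis exactly once."""
    if density_class not in DENSITY_CLASSES:
        raise ValidationError(f"unknown density class {density_class!r}")
    if distribution_class not in DISTRIBUTION_CLASSES:
        raise ValidationError(f"unknown distribution class {distribution_class!r}")
    t = templates if templates is not None else _default_templates()
    parts = [t["distribution"][distribution_class], t["density"][density_class]]
    areas = abnormal_areas or []
    if areas:
        parts.extend(t["abnormal_area"].format(region=a) for a in areas)
    else:
        parts.append(t["no_abnormal"])
    return " ".join(p.strip() for p in parts)


# ------------------------------------------------------------------ label I/O
def _infer_dialect(path: Path, dialect: str | None) -> str:
    if dialect is not None:
        return dialect
    return "xlsx" if path.suffix.lower() in (".xlsx", ".xls") else "csv"


def write_label_table(table: LabelTable, path: str | Path, dialect: str | None = None) -> None:
    path = Path(path)
    df = pd.DataFrame(
        [
            {
                "image_id": r.image_id,
                "caption": r.caption,
                "density_class": r.density_class,
                "distribution_class": r.distribution_class,
                "abnormal_areas": _AREA_SEP.join(r.abnormal_areas),
            }
            for r in table.rows
        ],
        columns=_COLUMNS,
    )
    if _infer_dialect(path, dialect) == "xlsx":
        df.to_excel(path, index=False)
    else:
        df.to_csv(path, index=False, lineterminator="\n")


def read_label_table(path: str | Path, dialect: str | None = None) -> LabelTable:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        if _infer_dialect(path, dialect) == "xlsx":
            df = pd.read_excel(path)
        else:
            df = pd.read_csv(path)
    except (pd.errors.EmptyDataError, ValueError) as exc:
        raise FormatError(f"cannot parse label table {path}: {exc}") from exc
    missing = set(_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"label table {path} missing columns: {sorted(missing)}")
    rows = []
    for rec in df.to_dict(orient="records"):
        areas = rec["abnormal_areas"]
        areas = [] if (pd.isna(areas) or areas == "") else str(areas).split(_AREA_SEP)
        rows.append(TextLabel(str(rec["image_id"]), str(rec["caption"]),
                              str(rec["density_class"]), str(rec["distribution_class"]), areas))
    return LabelTable(rows)


# ------------------------------------------------------------------ embedding
def _stub_token_vector(token: str, seed: int, dim: int) -> np.ndarray:
    """Deterministic embedding of one token: depends only on (token, seed, dim)."""
    digest = hashlib.blake2b(f"{seed}:{token}".encode(), digest_size=8).digest()
    rng = np.random.default_rng(int.from_bytes(digest, "little"))
    return rng.standard_normal(dim)


def embed_text(caption: str, embedder: str = "stub", max_tokens: int = 32,
               seed: int = 0, dim: int = 768) -> np.ndarray:
    """Embed a caption as an (n_tokens, dim) array, truncated to max_tokens."""
    if not caption:
        raise ValidationError("caption must be non-empty")
    if embedder == "stub":
        tokens = caption.split()[:max_tokens]
        return np.stack([_stub_token_vector(t, seed, dim) for t in tokens])
    if embedder == "pretrained":
        try:
            import transformers  # noqa: F401
        except ImportError as exc:
            raise BackendUnavailableError(
                "pretrained text encoder requested but the 'transformers' package "
                "is not installed; use embedder='stub' for offline operation"
            ) from exc
        return _pretrained_embed(caption, max_tokens)
    raise ValidationError(f"unknown embedder {embedder!r}")


def _pretrained_embed(caption: str, max_tokens: int) -> np.ndarray:  # pragma: no cover
    from transformers import AutoModel, AutoTokenizer

    tok = AutoTokenizer.from_pretrained("bert-base-uncased")
    model = AutoModel.from_pretrained("bert-base-uncased")
    enc = tok(caption, truncation=True, max_length=max_tokens, return_tensors="pt")
    out = model(**enc).last_hidden_state[0]
    return out.detach().numpy().astype(float)
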