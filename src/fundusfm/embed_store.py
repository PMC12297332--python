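"""Embedding extraction, persistence, checkpoint stripping, and storage
accounting.

Embeddings are kept as a dense float32 matrix with a sidecar CSV index of
image ids — the simplest portable layout for a vector-database workflow.
Checkpoint stripping removes training-only tensors (optimizer moments,
projector head, corruption token) and keeps only what inference needs, which
never changes the embeddings a model produces.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .model import TokenStudent, forward_tokens
from .prep import NormalisationScheme, normalize, resize_image
from .vit import BACKBONE_PREFIXES

__all__ = [
    "EmbeddingMatrix",
    "compute_embeddings",
    "save_embeddings",
    "load_embeddings",
    "strip_checkpoint",
    "embedding_storage",
]


@dataclass
class EmbeddingMatrix:
    """[n x d] float32 matrix plus image-id index."""

    values: np.ndarray
    ids: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        if len(self.ids) != self.values.shape[0]:
            raise ValueError("index length must match row count")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("image ids must be unique")
        if not np.isfinite(self.values).all():
            raise ValueError("embeddings must be finite")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]


def compute_embeddings(model: TokenStudent, images, scheme: NormalisationScheme,
                       batch_size: int = 16, ids: list[str] | None = None
                       ) -> EmbeddingMatrix:
    """One d-vector per image (pooling per the model config); images are
    resized to the model's input side and normalised first. The result is
    independent of batch size up to float tolerance."""
    side = model.config.image_side
    stack = []
    kept_ids = []
    for i, img in enumerate(images):
        px = np.asarray(getattr(img, "pixels", img), dtype=np.float32)
        img_id = ids[i] if ids is not None else getattr(img, "image_id", "") or f"img{i:06d}"
        if px.ndim != 3 or px.shape[2] != 3:
            continue  # unreadable row skipped
        if px.shape[0] != side or px.shape[1] != side:
            px = resize_image(px, (side, side))
        stack.append(normalize(px, scheme))
        kept_ids.append(img_id)
    rows = []
    for start in range(0, len(stack), batch_size):
        batch = np.stack(stack[start:start + batch_size])
        tok = forward_tokens(model, batch)
        rows.append(tok.embedding(model.config.embedding))
    values = np.vstack(rows) if rows else np.zeros((0, model.config.embed_dim), np.float32)
    return EmbeddingMatrix(values=values, ids=kept_ids)


def save_embeddings(emb: EmbeddingMatrix, path) -> Path:
    """Dense float32 binary matrix + sidecar CSV index (same stem, .index.csv)."""
    path = Path(path)
    emb.values.astype(np.float32).tofile(path)
    pd.DataFrame({"image_id": emb.ids, "row": range(emb.n), "d": emb.d}).to_csv(
        path.with_suffix(path.suffix + ".index.csv"), index=False
    )
    return path


def load_embeddings(path) -> EmbeddingMatrix:
    path = Path(path)
    index = pd.read_csv(path.with_suffix(path.suffix + ".index.csv"))
    d = int(index["d"].iloc[0])
    values = np.fromfile(path, dtype=np.float32).reshape(-1, d)
    return EmbeddingMatrix(values=values, ids=index["image_id"].tolist())


def strip_checkpoint(path) -> Path:
    """Remove training-only tensors from an .npz checkpoint, leaving only the
    inference backbone. Idempotent; embeddings from original and stripped
    checkpoints are identical."""
    path = Path(path)
    with np.load(path) as npz:
        state = {k: npz[k] for k in npz.files}
    kept = {k: v for k, v in state.items() if k.startswith(BACKBONE_PREFIXES)}
    if not kept:
        raise ValueError(f"no recognizable backbone weight block in {path}")
    if path.name.endswith(".stripped.npz"):
        out = path
    else:
        out = path.with_name(path.name[:-len(".npz")] + ".stripped.npz"
                             if path.name.endswith(".npz") else path.name + ".stripped.npz")
    np.savez(out, **kept)
    return out


def embedding_storage(n_vectors: int, d: int, bytes_per_value: int = 4,
                      d_reference: int = 1024) -> tuple[int, float]:
    """Total bytes for n dense vectors and the storage fold ratio relative to
    a reference dimensionality (1024-d vs 384-d gives 2.67)."""
    if n_vectors <= 0 or d <= 0 or bytes_per_value <= 0:
        raise ValueError("arguments must be positive")
    total = n_vectors * d * bytes_per_value
    fold = round(d_reference / d, 2)
    return total, fold
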