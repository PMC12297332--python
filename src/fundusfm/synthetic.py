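"""Synthetic fundus-like fixtures: images, patient-structured label tables,
and Gaussian-blob embedding matrices.

The generator emulates the geometry the preprocessing and pretraining code
must handle — a circular retina disc on pure black background, dark vessel
polylines, a bright optic disc, grade-dependent bright lesion specks of 2-4
pixel radius (class signal deliberately carried by small structures),
optional horizontal black side bars, and optional top/bottom truncation —
with exact ground-truth geometry recorded per image. Everything is fully
deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "FundusImage",
    "SyntheticSpec",
    "GroundTruth",
    "generate_fundus_image",
    "generate_dataset",
    "generate_embedding_blobs",
    "save_dataset",
]


@dataclass
class FundusImage:
    """HxWx3 float pixel array in [0, 1] with provenance metadata."""

    pixels: np.ndarray
    image_id: str = ""
    meta: dict = field(default_factory=dict)

    @property
    def shape(self):
        return self.pixels.shape


@dataclass(frozen=True)
class SyntheticSpec:
    image_side: int = 128
    disc_radius_frac: float = 0.42
    vessel_count: int = 6
    lesion_counts_per_grade: tuple[int, ...] = (0, 3, 8, 16, 30)
    bar_prob: float = 0.3
    crop_prob: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.bar_prob <= 1.0 and 0.0 <= self.crop_prob <= 1.0):
            raise ValueError("probabilities must be in [0, 1]")
        if any(b <= a for a, b in zip(self.lesion_counts_per_grade,
                                      self.lesion_counts_per_grade[1:])):
            raise ValueError("lesion counts must be strictly increasing with grade")
        if self.image_side < 32:
            raise ValueError("image_side must be at least 32")


@dataclass
class GroundTruth:
    disc_center: tuple[int, int]  # (row, col)
    disc_radius: int
    grade: int
    binary_label: int
    patient_id: str = ""
    truncated_rows: tuple[int, int] = (0, 0)  # rows removed at (top, bottom)


_DISC_COLOR = np.array([0.72, 0.34, 0.10], dtype=np.float32)
_VESSEL_COLOR = np.array([0.30, 0.08, 0.05], dtype=np.float32)
_OPTIC_COLOR = np.array([0.95, 0.85, 0.55], dtype=np.float32)
_LESION_COLOR = np.array([0.98, 0.92, 0.20], dtype=np.float32)
_MIN_INTENSITY = 0.04  # every disc pixel stays strictly above black


def _draw_disc(canvas, center, radius, rng):
    h, w = canvas.shape[:2]
    rr, cc = np.ogrid[:h, :w]
    dist2 = (rr - center[0]) ** 2 + (cc - center[1]) ** 2
    mask = dist2 <= radius ** 2
    shade = 1.0 - 0.35 * np.sqrt(dist2[mask]) / radius
    canvas[mask] = _DISC_COLOR * shade[:, None]
    canvas[mask] += rng.normal(0.0, 0.015, size=(int(mask.sum()), 3)).astype(np.float32)
    return mask


def _stamp_circle(canvas, center, radius, color, disc_mask):
    h, w = canvas.shape[:2]
    r0 = max(0, center[0] - radius)
    r1 = min(h, center[0] + radius + 1)
    c0 = max(0, center[1] - radius)
    c1 = min(w, center[1] + radius + 1)
    rr, cc = np.ogrid[r0:r1, c0:c1]
    m = (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius ** 2
    m &= disc_mask[r0:r1, c0:c1]
    canvas[r0:r1, c0:c1][m] = color


def _draw_vessels(canvas, center, radius, count, rng, disc_mask):
    h, w = canvas.shape[:2]
    for _ in range(count):
        angle = rng.uniform(0, 2 * np.pi)
        pos = np.array(center, dtype=np.float64)
        step = np.array([np.sin(angle), np.cos(angle)])
        for _ in range(int(radius * 1.4)):
            step += rng.normal(0, 0.25, size=2)
            step /= np.linalg.norm(step) + 1e-9
            pos += step
            r, c = int(round(pos[0])), int(round(pos[1]))
            if not (0 <= r < h and 0 <= c < w) or not disc_mask[r, c]:
                break
            canvas[max(0, r - 1):r + 1, max(0, c - 1):c + 1] = _VESSEL_COLOR


def generate_fundus_image(spec: SyntheticSpec, grade: int,
                          rng: np.random.Generator | None = None
                          ) -> tuple[FundusImage, GroundTruth]:
    """Render one fundus-like image of the given severity grade (0-4)."""
    if not 0 <= grade < len(spec.lesion_counts_per_grade):
        raise ValueError(f"grade must be in 0..{len(spec.lesion_counts_per_grade) - 1}")
    if spec.disc_radius_frac >= 0.5 and spec.bar_prob > 0:
        raise ValueError("disc_radius_frac >= 0.5 with side bars enabled: "
                         "disc would exceed the frame")
    rng = rng if rng is not None else np.random.default_rng(spec.seed)

    side = spec.image_side
    radius = int(round(spec.disc_radius_frac * side))
    center = (side // 2, side // 2)
    canvas = np.zeros((side, side, 3), dtype=np.float32)
    disc_mask = _draw_disc(canvas, center, radius, rng)
    _draw_vessels(canvas, center, radius, spec.vessel_count, rng, disc_mask)

    optic_center = (center[0], center[1] + int(radius * 0.45))
    _stamp_circle(canvas, optic_center, max(2, radius // 6), _OPTIC_COLOR, disc_mask)

    n_lesions = spec.lesion_counts_per_grade[grade]
    for _ in range(n_lesions):
        ang = rng.uniform(0, 2 * np.pi)
        rad = rng.uniform(0.1, 0.85) * radius
        lr = int(round(center[0] + rad * np.sin(ang)))
        lc = int(round(center[1] + rad * np.cos(ang)))
        _stamp_circle(canvas, (lr, lc), int(rng.integers(2, 5)), _LESION_COLOR, disc_mask)

    canvas[disc_mask] = np.clip(canvas[disc_mask], _MIN_INTENSITY, 1.0)

    # acquisition artifacts: horizontal black side bars / vertical truncation
    row_off = 0
    trunc = (0, 0)
    if rng.random() < spec.bar_prob:
        bar = int(rng.integers(side // 10, side // 4 + 1))
        canvas = np.pad(canvas, ((0, 0), (bar, bar), (0, 0)))
        center = (center[0], center[1] + bar)
    if rng.random() < spec.crop_prob:
        cut = int(rng.integers(1, max(2, int(side * 0.12))))
        canvas = canvas[cut:canvas.shape[0] - cut]
        row_off = cut
        trunc = (cut, cut)

    truth = GroundTruth(
        disc_center=(center[0] - row_off, center[1]),
        disc_radius=radius,
        grade=grade,
        binary_label=int(grade >= 1),
        truncated_rows=trunc,
    )
    img = FundusImage(pixels=canvas, meta={"grade": grade})
    return img, truth


def generate_dataset(spec: SyntheticSpec, n_patients: int, images_per_patient: int,
                     grade_distribution, seed: int = 0
                     ) -> tuple[list[FundusImage], pd.DataFrame]:
    """Patient-structured dataset: all images of one patient share patient_id
    and grade. Returns (images, label table with image_id / patient_id /
    grade / binary_label)."""
    probs = np.asarray(grade_distribution, dtype=float)
    if probs.size == 0:
        raise ValueError("grade distribution is empty")
    if abs(probs.sum() - 1.0) > 1e-8:
        raise ValueError("grade distribution must sum to 1")
    rng = np.random.default_rng(seed)
    images: list[FundusImage] = []
    rows = []
    for p in range(n_patients):
        patient_id = f"pat{p:05d}"
        grade = int(rng.choice(probs.size, p=probs))
        for j in range(images_per_patient):
            img, truth = generate_fundus_image(spec, grade, rng)
            img.image_id = f"{patient_id}_img{j}"
            truth.patient_id = patient_id
            img.meta["ground_truth"] = truth
            images.append(img)
            rows.append({
                "image_id": img.image_id,
                "patient_id": patient_id,
                "grade": grade,
                "binary_label": int(grade >= 1),
            })
    return images, pd.DataFrame(rows)


def generate_embedding_blobs(n_per_class: int, d: int, separation: float,
                             seed: int = 0):
    """Two isotropic unit-variance Gaussian clouds whose means are
    `separation` apart: a fixture for probe and bootstrap machinery.
    Returns (EmbeddingMatrix, labels)."""
    from .embed_store import EmbeddingMatrix

    if n_per_class < 2:
        raise ValueError("n_per_class must be at least 2")
    if d < 2:
        raise ValueError("d must be at least 2")
    if separation < 0:
        raise ValueError("separation must be nonnegative")
    rng = np.random.default_rng(seed)
    direction = np.zeros(d)
    direction[0] = 1.0
    shift = direction * separation
    x0 = rng.normal(size=(n_per_class, d))
    x1 = rng.normal(size=(n_per_class, d)) + shift
    values = np.vstack([x0, x1]).astype(np.float32)
    labels = np.concatenate([np.zeros(n_per_class, int), np.ones(n_per_class, int)])
    ids = [f"blob{i:05d}" for i in range(2 * n_per_class)]
    return EmbeddingMatrix(values=values, ids=ids), labels


def save_dataset(images: list[FundusImage], table: pd.DataFrame, out_dir) -> Path:
    """Write PNG images (8-bit) and the label table as CSV."""
    from PIL import Image

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for img in images:
        arr = np.clip(img.pixels * 255.0, 0, 255).astype(np.uint8)
        Image.fromarray(arr).save(out / f"{img.image_id}.png")
    table.to_csv(out / "labels.csv", index=False)
    return out
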