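"""Fundus preprocessing: fundus-area detection, aspect-preserving square
crop/pad, resize, per-model normalisation, and patient-level splitting.

Colour fundus photographs are a bright circular retina disc on a black
background; datasets differ in how much horizontal black space surrounds the
disc and whether the disc is truncated at the top and bottom. The square
pipeline detects the disc, crops to it, pads the shorter dimension with black
to restore a square aspect, and resizes — so the disc is never squashed.

Detection uses the simplest robust rule for dark-background photographs:
grayscale as the channel mean, a threshold at a fraction of the maximum
intensity (default 0.05), and the largest 4-connected component.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.measure import label, regionprops
from skimage.transform import resize as _sk_resize

__all__ = [
    "CropBox",
    "PrepConfig",
    "NormalisationScheme",
    "GREEN_SCHEME",
    "IMAGENET_SCHEME",
    "detect_fundus_region",
    "standardize_to_square",
    "resize_image",
    "normalize",
    "patient_level_split",
]


@dataclass(frozen=True)
class CropBox:
    """0-based half-open pixel box."""

    row_start: int
    row_end: int
    col_start: int
    col_end: int

    def __post_init__(self):
        if not (0 <= self.row_start < self.row_end and 0 <= self.col_start < self.col_end):
            raise ValueError(f"degenerate crop box {self}")

    @property
    def height(self) -> int:
        return self.row_end - self.row_start

    @property
    def width(self) -> int:
        return self.col_end - self.col_start


@dataclass(frozen=True)
class PrepConfig:
    target_side: int = 1024
    detection_threshold: float = 0.05
    jpeg_quality: int = 98
    interpolation: str = "bilinear"

    def __post_init__(self):
        if self.target_side <= 0:
            raise ValueError("target_side must be positive")
        if not 1 <= self.jpeg_quality <= 100:
            raise ValueError("jpeg_quality must be in 1..100")


@dataclass(frozen=True)
class NormalisationScheme:
    mean: tuple[float, float, float]
    std: tuple[float, float, float]

    def __post_init__(self):
        if any(s <= 0 for s in self.std):
            raise ValueError("std must be strictly positive")


# the model trained here only needs 0.5; the ImageNet constants are what the
# large pretrained comparators use
GREEN_SCHEME = NormalisationScheme(mean=(0.5, 0.5, 0.5), std=(0.5, 0.5, 0.5))
IMAGENET_SCHEME = NormalisationScheme(
    mean=(0.485, 0.456, 0.406), std=(0.229, 0.224, 0.225)
)

_ORDERS = {"nearest": 0, "bilinear": 1, "bicubic": 3}


def _pixels(image) -> np.ndarray:
    px = getattr(image, "pixels", image)
    px = np.asarray(px, dtype=np.float32)
    if px.ndim != 3 or px.shape[2] != 3:
        raise ValueError("expected an HxWx3 image")
    return px


def detect_fundus_region(image, threshold: float = 0.05) -> CropBox:
    """Tightest box containing the largest 4-connected component of pixels
    whose gray intensity exceeds threshold x max intensity."""
    px = _pixels(image)
    gray = px.mean(axis=2)
    peak = gray.max()
    mask = gray > threshold * peak
    if peak <= 0 or not mask.any():
        raise ValueError("empty fundus: no pixel above detection threshold")
    lab = label(mask, connectivity=1)
    regions = regionprops(lab)
    biggest = max(regions, key=lambda r: r.area)
    r0, c0, r1, c1 = biggest.bbox
    return CropBox(row_start=r0, row_end=r1, col_start=c0, col_end=c1)


def resize_image(pixels: np.ndarray, shape: tuple[int, int],
                 interpolation: str = "bilinear") -> np.ndarray:
    order = _ORDERS[interpolation]
    out = _sk_resize(pixels, shape + (pixels.shape[2],), order=order,
                     mode="constant", cval=0.0, anti_aliasing=False,
                     preserve_range=True)
    return np.clip(out, 0.0, 1.0).astype(np.float32)


def standardize_to_square(image, box: CropBox, config: PrepConfig | None = None) -> np.ndarray:
    """Crop to the detected box, pad the shorter dimension symmetrically with
    black to a square (odd padding: the extra row/column goes to the
    bottom/right), then resize to target_side. The disc aspect ratio is
    preserved."""
    config = config or PrepConfig()
    px = _pixels(image)
    h, w = px.shape[:2]
    if box.row_end > h or box.col_end > w:
        raise ValueError("crop box exceeds image bounds")
    crop = px[box.row_start:box.row_end, box.col_start:box.col_end]
    ch, cw = crop.shape[:2]
    if cw > ch:  # wider than tall: pad rows
        total = cw - ch
        top, bottom = total // 2, total - total // 2
        crop = np.pad(crop, ((top, bottom), (0, 0), (0, 0)))
    elif ch > cw:  # taller than wide: pad columns
        total = ch - cw
        left, right = total // 2, total - total // 2
        crop = np.pad(crop, ((0, 0), (left, right), (0, 0)))
    return resize_image(crop, (config.target_side, config.target_side),
                        config.interpolation)


def normalize(image, scheme: NormalisationScheme) -> np.ndarray:
    """Per-channel (x - mean) / std on an image scaled to [0, 1]."""
    px = _pixels(image)
    mean = np.asarray(scheme.mean, dtype=np.float32)
    std = np.asarray(scheme.std, dtype=np.float32)
    return (px - mean) / std


def patient_level_split(label_table: pd.DataFrame, train_fraction: float = 0.8,
                        seed: int = 0) -> tuple[list, list]:
    """Split image ids into train/test over distinct patient_ids so no patient
    appears on both sides. Returns (train_image_ids, test_image_ids)."""
    if "patient_id" not in label_table.columns:
        raise ValueError("label table needs a patient_id column")
    patients = label_table["patient_id"].unique()
    if len(patients) < 2:
        raise ValueError("need at least 2 patients to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(patients))
    n_train = int(round(train_fraction * len(patients)))
    n_train = min(max(n_train, 1), len(patients) - 1)
    train_patients = set(patients[order[:n_train]])
    in_train = label_table["patient_id"].isin(train_patients)
    id_col = "image_id" if "image_id" in label_table.columns else label_table.columns[0]
    return (
        label_table.loc[in_train, id_col].tolist(),
        label_table.loc[~in_train, id_col].tolist(),
    )
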