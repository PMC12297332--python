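"""Training-time stochastic augmentation for pretraining.

The recipe: slight colour jitter and rotation 25% of the time; black padding
of the left and right sides by a random number of pixels in [33, 150] 10% of
the time (simulating poorly cropped images); a random global rescale between
80% and 120%; then one of three ways, chosen uniformly, of reaching the
square target resolution — a plain resize, a random resized crop with scale
70-100%, or a centre crop after scaling the image up by 30%.

The magnitudes of "slight" jitter and rotation are configurable (defaults:
brightness/contrast/saturation factors within +-0.1, rotation within +-10
degrees). Left and right pad widths are sampled independently. Every draw
comes from the caller's generator, so a fixed state reproduces the pipeline
bit for bit; sampling the plan is split from applying it so the branch
statistics can be audited cheaply.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import rotate as _sk_rotate

from .prep import resize_image

__all__ = ["AugmentConfig", "AugmentPlan", "sample_augment_plan", "augment_image"]

MODES = ("standard", "random_resized_crop", "center_crop")


@dataclass(frozen=True)
class AugmentConfig:
    jitter_rot_prob: float = 0.25
    side_pad_prob: float = 0.10
    side_pad_range: tuple[int, int] = (33, 150)
    scale_range: tuple[float, float] = (0.80, 1.20)
    target_side: int = 392
    jitter_strength: float = 0.1
    rotation_degrees: float = 10.0
    rrc_scale: tuple[float, float] = (0.70, 1.00)
    center_upscale: float = 1.3
    modes: tuple[str, ...] = MODES

    def __post_init__(self):
        for p in (self.jitter_rot_prob, self.side_pad_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")
        for lo, hi in (self.side_pad_range, self.scale_range, self.rrc_scale):
            if lo > hi:
                raise ValueError("ranges must be ordered")
        if any(m not in MODES for m in self.modes):
            raise ValueError(f"modes must be drawn from {MODES}")


@dataclass
class AugmentPlan:
    do_jitter: bool
    brightness: float
    contrast: float
    saturation: float
    angle: float
    do_pad: bool
    pad_left: int
    pad_right: int
    scale: float
    mode: str
    rrc_area: float
    rrc_top: float
    rrc_left: float


def sample_augment_plan(config: AugmentConfig, rng: np.random.Generator) -> AugmentPlan:
    """Draw every stochastic branch independently from `rng` (fixed draw
    order, so identical states give identical plans)."""
    do_jitter = rng.random() < config.jitter_rot_prob
    s = config.jitter_strength
    brightness, contrast, saturation = rng.uniform(-s, s, size=3)
    angle = rng.uniform(-config.rotation_degrees, config.rotation_degrees)
    do_pad = rng.random() < config.side_pad_prob
    lo, hi = config.side_pad_range
    pad_left = int(rng.integers(lo, hi + 1))
    pad_right = int(rng.integers(lo, hi + 1))
    scale = rng.uniform(*config.scale_range)
    mode = config.modes[int(rng.integers(len(config.modes)))]
    rrc_area = rng.uniform(*config.rrc_scale)
    rrc_top = rng.random()
    rrc_left = rng.random()
    return AugmentPlan(do_jitter, brightness, contrast, saturation, angle,
                       do_pad, pad_left, pad_right, scale, mode,
                       rrc_area, rrc_top, rrc_left)


def _jitter(px: np.ndarray, plan: AugmentPlan) -> np.ndarray:
    out = px * (1.0 + plan.brightness)
    mean = out.mean()
    out = mean + (out - mean) * (1.0 + plan.contrast)
    gray = out.mean(axis=2, keepdims=True)
    out = gray + (out - gray) * (1.0 + plan.saturation)
    return np.clip(out, 0.0, 1.0)


def apply_augment_plan(image, plan: AugmentPlan, config: AugmentConfig) -> np.ndarray:
    px = np.asarray(getattr(image, "pixels", image), dtype=np.float32)
    if min(px.shape[:2]) < 32:
        raise ValueError("image must be at least 32 px per side")
    if min(px.shape[:2]) < 64:  # degenerate tiny inputs are upscaled first
        f = 64 / min(px.shape[:2])
        px = resize_image(px, (round(px.shape[0] * f), round(px.shape[1] * f)))

    if plan.do_jitter:
        px = _jitter(px, plan)
        px = _sk_rotate(px, plan.angle, resize=False, mode="constant",
                        cval=0.0, preserve_range=True).astype(np.float32)
    if plan.do_pad:
        px = np.pad(px, ((0, 0), (plan.pad_left, plan.pad_right), (0, 0)))
    if plan.scale != 1.0:
        h, w = px.shape[:2]
        px = resize_image(px, (max(1, round(h * plan.scale)),
                               max(1, round(w * plan.scale))))

    t = config.target_side
    if plan.mode == "standard":
        return resize_image(px, (t, t))
    if plan.mode == "random_resized_crop":
        h, w = px.shape[:2]
        frac = np.sqrt(plan.rrc_area)
        ch = max(1, round(h * frac))
        cw = max(1, round(w * frac))
        top = int(plan.rrc_top * (h - ch + 1))
        left = int(plan.rrc_left * (w - cw + 1))
        return resize_image(px[top:top + ch, left:left + cw], (t, t))
    # centre crop after upscaling by 30%
    big = round(t * config.center_upscale)
    px = resize_image(px, (big, big))
    off = (big - t) // 2
    return px[off:off + t, off:off + t]


def augment_image(image, config: AugmentConfig, rng: np.random.Generator) -> np.ndarray:
    """Full stochastic pipeline; always returns a target_side-square float
    image in [0, 1]."""
    plan = sample_augment_plan(config, rng)
    return apply_augment_plan(image, plan, config)
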