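"""Token Reconstruction: corruption sampling, pixel noise, frozen-teacher MSE
objective, AdamW with warmup/cosine/cooldown schedule, and the training loop.

The objective: a frozen teacher (a parameter-identical copy of the student at
initialisation) sees clean images; the student sees corrupted versions — a
per-image random subset of patch embeddings replaced by a trainable
corruption token (ratio ~ Uniform(0, 1/3)) plus pixel-wise Gaussian noise
(sigma 0.2, applied in normalised intensity space) — and is penalised by the
mean squared error between its projected output tokens and the teacher's
tokens. The last image in each batch is kept uncorrupted so the student stays
robust to the absence of corruption.

Decisions the loop commits to: both corruption modes are applied jointly to
every image except the batch's last; the corruption ratio is drawn per image;
pixel noise is added after normalisation; the teacher is frozen at
initialisation with no momentum update; weight decay is decoupled (AdamW) and
skipped for bias parameters only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor
from .model import TokenSet, TokenStudent

__all__ = [
    "CorruptionSpec",
    "CorruptionPlan",
    "TrainConfig",
    "sample_corruption_mask",
    "sample_corruption_plan",
    "add_pixel_noise",
    "token_reconstruction_loss",
    "lr_at_epoch",
    "AdamW",
    "clip_gradients",
    "train",
]


@dataclass(frozen=True)
class CorruptionSpec:
    """Corruption applied to the student's inputs."""

    ratio_upper: float = 1.0 / 3.0  # ratio ~ Uniform(0, ratio_upper), per image
    noise_sigma: float = 0.2        # pixel noise N(0, sigma^2) in normalised space
    keep_last_clean: bool = True    # last image of each batch is uncorrupted

    def __post_init__(self):
        if not 0.0 <= self.ratio_upper <= 1.0:
            raise ValueError("ratio_upper must be in [0, 1]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be nonnegative")


@dataclass
class CorruptionPlan:
    """Per-image boolean patch masks plus per-image pixel-noise flags."""

    masks: np.ndarray        # [B, n_patches] bool
    noise_flags: np.ndarray  # [B] bool


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 120
    batch_size: int = 128
    peak_lr: float = 5e-5
    min_lr: float = 5e-9
    beta1: float = 0.9
    beta2: float = 0.99
    weight_decay: float = 5e-4
    warmup_epochs: int = 10
    cooldown_epochs: int = 20
    grad_clip_norm: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.warmup_epochs + self.cooldown_epochs >= self.epochs:
            raise ValueError("warmup + cooldown must be < epochs")
        if self.min_lr > self.peak_lr:
            raise ValueError("min_lr must be <= peak_lr")


def sample_corruption_mask(n_patches: int, spec: CorruptionSpec,
                           rng: np.random.Generator) -> np.ndarray:
    """Draw one per-image mask: ratio r ~ Uniform(0, ratio_upper), then
    round(r * n_patches) patch positions chosen uniformly without
    replacement."""
    if n_patches <= 0:
        raise ValueError("n_patches must be positive")
    r = rng.uniform(0.0, spec.ratio_upper)
    k = int(round(r * n_patches))
    mask = np.zeros(n_patches, dtype=bool)
    if k:
        mask[rng.choice(n_patches, size=k, replace=False)] = True
    return mask


def sample_corruption_plan(batch_size: int, n_patches: int, spec: CorruptionSpec,
                           rng: np.random.Generator) -> CorruptionPlan:
    masks = np.stack([sample_corruption_mask(n_patches, spec, rng)
                      for _ in range(batch_size)])
    noise = np.full(batch_size, spec.noise_sigma > 0, dtype=bool)
    if spec.keep_last_clean and batch_size:
        masks[-1] = False
        noise[-1] = False
    return CorruptionPlan(masks=masks, noise_flags=noise)


def add_pixel_noise(images: np.ndarray, sigma: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Add i.i.d. Gaussian(0, sigma^2) noise element-wise (identity for
    sigma=0). Intended for images already in normalised intensity space."""
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    images = np.asarray(images, dtype=np.float32)
    if sigma == 0:
        return images.copy()
    return images + rng.normal(0.0, sigma, size=images.shape).astype(np.float32)


def token_reconstruction_loss(student, teacher):
    """Mean over all tokens and dimensions of the squared difference.

    Accepts TokenSets, arrays, or autodiff Tensors (the Tensor path is used
    during training so gradients flow to the student only).
    """
    s = student.tokens if isinstance(student, TokenSet) else student
    t = teacher.tokens if isinstance(teacher, TokenSet) else teacher
    s_shape = s.shape if isinstance(s, Tensor) else np.shape(s)
    t_shape = t.shape if isinstance(t, Tensor) else np.shape(t)
    if tuple(s_shape) != tuple(t_shape):
        raise ValueError(f"token shape mismatch: {s_shape} vs {t_shape}")
    if isinstance(s, Tensor):
        diff = s - (t if isinstance(t, Tensor) else Tensor(np.asarray(t)))
        return (diff * diff).mean()
    d = np.asarray(s, dtype=np.float64) - np.asarray(t, dtype=np.float64)
    return float(np.mean(d * d))


def lr_at_epoch(epoch: float, config: TrainConfig) -> float:
    """Linear warmup min->peak, cosine decay peak->min, then a constant-minimum
    cooldown over the final epochs."""
    if not 0 <= epoch < config.epochs:
        raise ValueError(f"epoch {epoch} outside [0, {config.epochs})")
    lo, hi = config.min_lr, config.peak_lr
    if epoch < config.warmup_epochs:
        return lo + (hi - lo) * epoch / config.warmup_epochs
    cos_end = config.epochs - config.cooldown_epochs
    if epoch >= cos_end:
        return lo
    t = (epoch - config.warmup_epochs) / (cos_end - config.warmup_epochs)
    return lo + 0.5 * (hi - lo) * (1.0 + math.cos(math.pi * t))


class AdamW:
    """Decoupled-weight-decay Adam over a named parameter dict.

    Weight decay is skipped for bias parameters (names ending in 'bias');
    every other tensor, including norms, tokens and the projector scale,
    is decayed.
    """

    def __init__(self, params: dict[str, Tensor], config: TrainConfig):
        self.params = params
        self.config = config
        self.m = {k: np.zeros_like(v.data) for k, v in params.items()}
        self.v = {k: np.zeros_like(v.data) for k, v in params.items()}
        self.t = 0
        self.eps = 1e-8

    def decayed(self, name: str) -> bool:
        return not name.endswith("bias")

    def step(self, lr: float) -> None:
        self.t += 1
        c = self.config
        bc1 = 1.0 - c.beta1 ** self.t
        bc2 = 1.0 - c.beta2 ** self.t
        for k, p in self.params.items():
            g = p.grad
            if g is None:
                continue
            self.m[k] = c.beta1 * self.m[k] + (1 - c.beta1) * g
            self.v[k] = c.beta2 * self.v[k] + (1 - c.beta2) * g * g
            update = (self.m[k] / bc1) / (np.sqrt(self.v[k] / bc2) + self.eps)
            if self.decayed(k) and c.weight_decay:
                p.data -= lr * c.weight_decay * p.data
            p.data -= lr * update

    def state_arrays(self) -> dict[str, np.ndarray]:
        """Optimizer moments under 'opt.m.*' / 'opt.v.*' names (for
        checkpointing; stripped for inference)."""
        out = {}
        for k in self.params:
            out[f"opt.m.{k}"] = self.m[k]
            out[f"opt.v.{k}"] = self.v[k]
        return out


def clip_gradients(params: dict[str, Tensor], max_norm: float) -> float:
    """Clip the global gradient norm in place; returns the post-clip norm."""
    sq = 0.0
    for p in params.values():
        if p.grad is not None:
            sq += float(np.sum(p.grad.astype(np.float64) ** 2))
    norm = math.sqrt(sq)
    if norm > max_norm > 0:
        scale = max_norm / (norm + 1e-12)
        for p in params.values():
            if p.grad is not None:
                p.grad *= scale
        return max_norm
    return norm


def _zero_grads(params: dict[str, Tensor]) -> None:
    for p in params.values():
        p.grad = None


def train(images: np.ndarray, model: TokenStudent, teacher: TokenStudent | None = None,
          train_config: TrainConfig | None = None,
          corruption: CorruptionSpec | None = None,
          n_steps: int | None = None,
          rng: np.random.Generator | None = None):
    """Run token-reconstruction pretraining on an in-memory image stack.

    `images`: [n, side, side, 3] normalised floats. The teacher defaults to a
    frozen copy of the student at entry; if supplied it must be
    parameter-identical in shape. Returns (model, history) where history has
    per-step 'loss', 'lr' and post-clip 'grad_norm' lists.
    """
    train_config = train_config or TrainConfig()
    corruption = corruption or CorruptionSpec()
    rng = rng or np.random.default_rng(train_config.seed)
    images = np.asarray(images, dtype=np.float32)
    n_images = images.shape[0]
    bs = min(train_config.batch_size, n_images)

    if teacher is None:
        teacher_state = model.state_dict()
        teacher = TokenStudent(model.config, seed=0)
        teacher.load_state_dict(teacher_state)
    else:
        mine = model.state_dict()
        theirs = teacher.state_dict()
        for k in mine:
            if k in theirs and mine[k].shape != theirs[k].shape:
                raise ValueError(f"teacher/student shape mismatch on {k}")
    for p in teacher.parameters().values():
        p.requires_grad = False

    steps_per_epoch = max(1, n_images // bs)
    if n_steps is None:
        n_steps = train_config.epochs * steps_per_epoch
    params = model.parameters()
    opt = AdamW(params, train_config)
    n_patches = model.config.n_patches

    history = {"loss": [], "lr": [], "grad_norm": []}
    for step in range(n_steps):
        idx = rng.choice(n_images, size=bs, replace=n_images < bs)
        batch = images[idx]

        teacher_tokens = teacher.forward_graph(batch).data  # clean, no grad needed

        plan = sample_corruption_plan(bs, n_patches, corruption, rng)
        noisy = batch.copy()
        if corruption.noise_sigma > 0:
            flagged = np.where(plan.noise_flags)[0]
            if flagged.size:
                noisy[flagged] = add_pixel_noise(noisy[flagged], corruption.noise_sigma, rng)

        _zero_grads(params)
        student_tokens = model.forward_graph(noisy, masks=plan.masks, project=True)
        loss = token_reconstruction_loss(student_tokens, Tensor(teacher_tokens))
        loss.backward()
        norm = clip_gradients(params, train_config.grad_clip_norm)

        epoch = min(step / steps_per_epoch, train_config.epochs - 1e-9)
        lr = lr_at_epoch(epoch, train_config)
        opt.step(lr)

        history["loss"].append(float(loss.data))
        history["lr"].append(lr)
        history["grad_norm"].append(norm)

    history["optimizer"] = opt
    return model, history
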