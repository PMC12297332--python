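"""Public model surface: configurable ViT student with register tokens,
corruption token and residual projector head.

The designated image embedding defaults to the class-token output; mean
pooling over patch tokens is available via ``BackboneConfig.embedding``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor
from .vit import BACKBONE_PREFIXES, Projector, VisionTransformer

__all__ = [
    "BackboneConfig",
    "TokenSet",
    "TokenStudent",
    "build_student",
    "forward_tokens",
    "apply_corruption",
    "student_output",
]


@dataclass(frozen=True)
class BackboneConfig:
    """Architecture of the student backbone.

    The default configuration is the small-ViT class: 384-dimensional tokens,
    four register tokens and a 392x392 input at patch size 14, giving
    (392/14)^2 + 1 + 4 = 789 tokens.
    """

    image_side: int = 392
    patch_side: int = 14
    embed_dim: int = 384
    depth: int = 12
    heads: int = 6
    n_registers: int = 4
    has_class_token: bool = True
    embedding: str = "class_token"  # or "mean_patch"

    def __post_init__(self):
        if self.image_side % self.patch_side:
            raise ValueError("image_side must be divisible by patch_side")
        if self.embed_dim % self.heads:
            raise ValueError("embed_dim must be divisible by heads")
        if self.embedding not in ("class_token", "mean_patch"):
            raise ValueError("embedding must be 'class_token' or 'mean_patch'")
        if self.embedding == "class_token" and not self.has_class_token:
            raise ValueError("class_token pooling requires has_class_token")

    @property
    def n_patches(self) -> int:
        return (self.image_side // self.patch_side) ** 2

    @property
    def n_tokens(self) -> int:
        return int(self.has_class_token) + self.n_registers + self.n_patches


@dataclass
class TokenSet:
    """Output tokens of the transformer, partitioned into class / register /
    patch blocks (patch block in row-major patch order)."""

    tokens: np.ndarray  # [B, n_tokens, d] or [n_tokens, d]
    n_class: int
    n_registers: int

    def __post_init__(self):
        if self.tokens.ndim == 2:
            self.tokens = self.tokens[None]

    @property
    def n_tokens(self) -> int:
        return self.tokens.shape[1]

    @property
    def embed_dim(self) -> int:
        return self.tokens.shape[2]

    @property
    def class_block(self) -> np.ndarray:
        return self.tokens[:, : self.n_class]

    @property
    def register_block(self) -> np.ndarray:
        return self.tokens[:, self.n_class : self.n_class + self.n_registers]

    @property
    def patch_block(self) -> np.ndarray:
        return self.tokens[:, self.n_class + self.n_registers :]

    def embedding(self, pooling: str = "class_token") -> np.ndarray:
        if pooling == "class_token":
            if not self.n_class:
                raise ValueError("no class token in this TokenSet")
            return self.class_block[:, 0]
        if pooling == "mean_patch":
            return self.patch_block.mean(axis=1)
        raise ValueError(f"unknown pooling {pooling!r}")


class TokenStudent:
    """The trainable student: backbone + corruption token + projector."""

    def __init__(self, config: BackboneConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        self.backbone = VisionTransformer(
            rng,
            image_side=config.image_side,
            patch_side=config.patch_side,
            embed_dim=config.embed_dim,
            depth=config.depth,
            heads=config.heads,
            n_registers=config.n_registers,
            has_class_token=config.has_class_token,
        )
        self.projector = Projector(rng, config.embed_dim)

    # -- parameter access --------------------------------------------------

    def parameters(self) -> dict[str, Tensor]:
        p = self.backbone.params()
        p.update(self.projector.params())
        return p

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray], strict: bool = False) -> list[str]:
        """Load tensors by name; returns the names that were not found in
        `state` (freshly initialised extras). Shape mismatches raise, listing
        every offending tensor."""
        params = self.parameters()
        bad = [
            f"{k}: checkpoint {tuple(np.shape(state[k]))} vs model {tuple(v.shape)}"
            for k, v in params.items()
            if k in state and tuple(np.shape(state[k])) != tuple(v.shape)
        ]
        if bad:
            raise ValueError("shape mismatch loading weights:\n  " + "\n  ".join(bad))
        missing = []
        for k, v in params.items():
            if k in state:
                v.data = np.asarray(state[k], dtype=np.float32).copy()
            else:
                missing.append(k)
        if strict and missing:
            raise ValueError(f"missing tensors: {missing}")
        return missing

    def save(self, path) -> None:
        np.savez(path, **self.state_dict())

    # -- forward passes ----------------------------------------------------

    def _check_images(self, images: np.ndarray) -> np.ndarray:
        images = np.asarray(images, dtype=np.float32)
        if images.ndim == 3:
            images = images[None]
        side = self.config.image_side
        if images.shape[1] != side or images.shape[2] != side:
            raise ValueError(
                f"expected {side}x{side} images, got {images.shape[1]}x{images.shape[2]}"
            )
        return images

    def forward_graph(self, images: np.ndarray, masks: np.ndarray | None = None,
                      project: bool = False) -> Tensor:
        """Differentiable forward: backbone tokens, optionally corrupted and
        passed through the residual projector."""
        images = self._check_images(images)
        if masks is not None:
            masks = np.asarray(masks, dtype=bool)
            if masks.ndim == 1:
                masks = masks[None]
            if masks.shape != (images.shape[0], self.config.n_patches):
                raise ValueError(
                    f"mask shape {masks.shape} does not match "
                    f"(batch={images.shape[0]}, n_patches={self.config.n_patches})"
                )
        tokens = self.backbone.forward(images, masks)
        if project:
            tokens = self.projector(tokens)
        return tokens

    def token_set(self, tokens: np.ndarray) -> TokenSet:
        return TokenSet(tokens, n_class=int(self.config.has_class_token),
                        n_registers=self.config.n_registers)


def build_student(config: BackboneConfig, init_weights=None, seed: int = 0) -> TokenStudent:
    """Construct a student model; if `init_weights` (path to an .npz archive
    or a state dict) is given, backbone tensors are loaded by name and extras
    (corruption token, projector) are freshly initialised."""
    model = TokenStudent(config, seed=seed)
    if init_weights is not None:
        if isinstance(init_weights, dict):
            state = init_weights
        else:
            with np.load(init_weights) as npz:
                state = {k: npz[k] for k in npz.files}
        if not any(k.startswith(BACKBONE_PREFIXES) for k in state):
            raise ValueError("no recognizable backbone weight block in init_weights")
        model.load_state_dict(state)
    return model


def forward_tokens(model: TokenStudent, images: np.ndarray) -> TokenSet:
    """Deterministic evaluation-mode forward pass of the backbone only."""
    tokens = model.forward_graph(images, masks=None, project=False)
    return model.token_set(tokens.data)


def apply_corruption(patch_embeddings: np.ndarray, mask: np.ndarray,
                     corruption_token: np.ndarray) -> np.ndarray:
    """Replace masked patch-embedding rows with the corruption token.

    Operates on a copy; unmasked rows are untouched and masked rows equal the
    corruption token exactly. Class/register tokens are not part of the input
    here and are therefore never corrupted.
    """
    patch_embeddings = np.asarray(patch_embeddings)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape[-1] != patch_embeddings.shape[-2]:
        raise ValueError(
            f"mask length {mask.shape[-1]} != n_patches {patch_embeddings.shape[-2]}"
        )
    out = patch_embeddings.copy()
    out[..., mask, :] = np.asarray(corruption_token, dtype=out.dtype)
    return out


def student_output(model: TokenStudent, images: np.ndarray, plan=None) -> TokenSet:
    """Student forward for the reconstruction objective: corrupted backbone
    tokens plus the scaled residual projector output."""
    masks = getattr(plan, "masks", plan)
    tokens = model.forward_graph(images, masks=masks, project=True)
    return model.token_set(tokens.data)
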