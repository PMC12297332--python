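"""Vision transformer with register tokens, built on the in-package autodiff.

The architecture is the standard pre-norm ViT: patch projection, a class
token, a configurable number of register tokens (extra tokens not tied to any
patch that carry global context), learned positional embeddings, transformer
blocks of multi-head self-attention + 4x MLP, and a final LayerNorm.

Two training-only extras are attached for the token-reconstruction objective:
a trainable corruption token that replaces selected patch embeddings, and a
residual projector head (LayerNorm - Linear - GELU - Linear) whose output is
scaled by a learnable element-wise vector (initialised to zero) and added to
the final tokens. With the scale at zero the projected output is exactly the
backbone output, which anchors the loss-is-zero-at-initialisation identity.
"""

from __future__ import annotations

from collections import OrderedDict

import numpy as np

from .autodiff import Tensor, concat, gelu, softmax

# tensor-name prefixes that belong to the inference backbone (everything else
# is training-only and removed by checkpoint stripping)
BACKBONE_PREFIXES = ("patch_embed.", "cls_token", "reg_tokens", "pos_embed", "blocks.", "norm.")

_INIT_STD = 0.02


def _param(rng: np.random.Generator, shape, std: float = _INIT_STD, zero: bool = False) -> Tensor:
    if zero:
        data = np.zeros(shape, dtype=np.float32)
    else:
        data = rng.normal(0.0, std, size=shape).astype(np.float32)
    return Tensor(data, requires_grad=True)


class Linear:
    def __init__(self, rng, d_in: int, d_out: int):
        self.weight = _param(rng, (d_in, d_out))
        self.bias = _param(rng, (d_out,), zero=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias

    def params(self, prefix: str) -> OrderedDict:
        return OrderedDict([(prefix + ".weight", self.weight), (prefix + ".bias", self.bias)])


class LayerNorm:
    def __init__(self, d: int, eps: float = 1e-6):
        self.weight = Tensor(np.ones(d, dtype=np.float32), requires_grad=True)
        self.bias = Tensor(np.zeros(d, dtype=np.float32), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc * ((var + self.eps) ** -0.5) * self.weight + self.bias

    def params(self, prefix: str) -> OrderedDict:
        return OrderedDict([(prefix + ".weight", self.weight), (prefix + ".bias", self.bias)])


class Attention:
    def __init__(self, rng, d: int, heads: int):
        if d % heads:
            raise ValueError("embed_dim must be divisible by heads")
        self.heads = heads
        self.head_dim = d // heads
        self.scale = self.head_dim ** -0.5
        self.qkv = Linear(rng, d, 3 * d)
        self.proj = Linear(rng, d, d)

    def __call__(self, x: Tensor) -> Tensor:
        b, n, d = x.shape
        qkv = self.qkv(x).reshape(b, n, 3, self.heads, self.head_dim)
        qkv = qkv.transpose(2, 0, 3, 1, 4)  # [3, B, h, N, dh]
        q, k, v = qkv[0], qkv[1], qkv[2]
        att = softmax((q @ k.transpose(0, 1, 3, 2)) * self.scale, axis=-1)
        out = (att @ v).transpose(0, 2, 1, 3).reshape(b, n, d)
        return self.proj(out)

    def params(self, prefix: str) -> OrderedDict:
        p = OrderedDict()
        p.update(self.qkv.params(prefix + ".qkv"))
        p.update(self.proj.params(prefix + ".proj"))
        return p


class Block:
    def __init__(self, rng, d: int, heads: int, mlp_ratio: int = 4):
        self.norm1 = LayerNorm(d)
        self.attn = Attention(rng, d, heads)
        self.norm2 = LayerNorm(d)
        self.fc1 = Linear(rng, d, mlp_ratio * d)
        self.fc2 = Linear(rng, mlp_ratio * d, d)

    def __call__(self, x: Tensor) -> Tensor:
        x = x + self.attn(self.norm1(x))
        return x + self.fc2(gelu(self.fc1(self.norm2(x))))

    def params(self, prefix: str) -> OrderedDict:
        p = OrderedDict()
        p.update(self.norm1.params(prefix + ".norm1"))
        p.update(self.attn.params(prefix + ".attn"))
        p.update(self.norm2.params(prefix + ".norm2"))
        p.update(self.fc1.params(prefix + ".mlp.fc1"))
        p.update(self.fc2.params(prefix + ".mlp.fc2"))
        return p


class Projector:
    """Residual MLP head: LayerNorm - Linear(d,d) - GELU - Linear(d,d)."""

    def __init__(self, rng, d: int):
        self.norm = LayerNorm(d)
        self.fc1 = Linear(rng, d, d)
        self.fc2 = Linear(rng, d, d)
        # learnable element-wise residual scale; zero-init so the head is an
        # exact no-op at the start of training
        self.scale = Tensor(np.zeros(d, dtype=np.float32), requires_grad=True)

    def __call__(self, tokens: Tensor) -> Tensor:
        return tokens + self.scale * self.fc2(gelu(self.fc1(self.norm(tokens))))

    def params(self) -> OrderedDict:
        p = OrderedDict()
        p.update(self.norm.params("projector.norm"))
        p.update(self.fc1.params("projector.fc1"))
        p.update(self.fc2.params("projector.fc2"))
        p["projector.scale"] = self.scale
        return p


def patchify(images: np.ndarray, patch_side: int) -> np.ndarray:
    """[B,H,W,3] -> [B, n_patches, patch_side*patch_side*3], row-major patches."""
    b, h, w, c = images.shape
    gh, gw = h // patch_side, w // patch_side
    x = images.reshape(b, gh, patch_side, gw, patch_side, c)
    x = x.transpose(0, 1, 3, 2, 4, 5)
    return np.ascontiguousarray(x).reshape(b, gh * gw, patch_side * patch_side * c)


class VisionTransformer:
    def __init__(self, rng, image_side: int, patch_side: int, embed_dim: int,
                 depth: int, heads: int, n_registers: int, has_class_token: bool = True):
        self.image_side = image_side
        self.patch_side = patch_side
        self.embed_dim = embed_dim
        self.n_registers = n_registers
        self.has_class_token = has_class_token
        self.n_patches = (image_side // patch_side) ** 2
        n_prefix = int(has_class_token) + n_registers

        self.patch_embed = Linear(rng, patch_side * patch_side * 3, embed_dim)
        self.cls_token = _param(rng, (1, embed_dim)) if has_class_token else None
        self.reg_tokens = _param(rng, (n_registers, embed_dim)) if n_registers else None
        self.pos_embed = _param(rng, (n_prefix + self.n_patches, embed_dim))
        self.blocks = [Block(rng, embed_dim, heads) for _ in range(depth)]
        self.norm = LayerNorm(embed_dim)
        self.corruption_token = _param(rng, (embed_dim,))

    def forward(self, images: np.ndarray, masks: np.ndarray | None = None) -> Tensor:
        """Run the backbone; `masks` ([B, n_patches] bool) selects patch
        embeddings replaced by the corruption token (class/register tokens are
        never corrupted)."""
        b = images.shape[0]
        patches = Tensor(patchify(np.asarray(images, dtype=np.float32), self.patch_side))
        x = self.patch_embed(patches)  # [B, N, d]
        if masks is not None:
            # constants kept float32 so the unmasked path is bit-identical to
            # a mask-free forward (anchor for the zero-loss-at-init identity)
            m = np.asarray(masks, dtype=np.float32)[:, :, None]
            x = x * Tensor(1.0 - m) + self.corruption_token * Tensor(m)
        zeros = Tensor(np.zeros((b, 1, self.embed_dim), dtype=np.float32))
        prefix = []
        if self.cls_token is not None:
            prefix.append(self.cls_token.reshape(1, 1, self.embed_dim) + zeros)
        if self.reg_tokens is not None:
            zr = Tensor(np.zeros((b, self.n_registers, self.embed_dim), dtype=np.float32))
            prefix.append(self.reg_tokens.reshape(1, self.n_registers, self.embed_dim) + zr)
        x = concat(prefix + [x], axis=1)
        x = x + self.pos_embed
        for blk in self.blocks:
            x = blk(x)
        return self.norm(x)

    def params(self) -> OrderedDict:
        p = OrderedDict()
        p.update(self.patch_embed.params("patch_embed"))
        if self.cls_token is not None:
            p["cls_token"] = self.cls_token
        if self.reg_tokens is not None:
            p["reg_tokens"] = self.reg_tokens
        p["pos_embed"] = self.pos_embed
        for i, blk in enumerate(self.blocks):
            p.update(blk.params(f"blocks.{i}"))
        p.update(self.norm.params("norm"))
        p["corruption_token"] = self.corruption_token
        return p
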