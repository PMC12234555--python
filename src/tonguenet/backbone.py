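"""Hierarchical mix-vision transformer encoder.

Produces a four-level feature pyramid at strides 4/8/16/32 from an RGB
image. Each stage is an overlapped patch embedding (a strided convolution)
followed by transformer blocks with spatial-reduction self-attention and a
mix-FFN (an MLP with a 3×3 depthwise convolution between the two linear
layers, which injects positional information without explicit positional
encodings).

The stage widths, depths, head counts and spatial-reduction ratios are all
configurable through :class:`BackboneConfig`; two presets are bundled —
``base`` (≈14M parameters for the full segmentation model) and ``tiny``
(CPU-friendly, for desk-scale experiments and the test suite).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .nn import Conv2d, LayerNorm, Linear, Module, ModuleList

__all__ = ["BackboneConfig", "FeaturePyramid", "MixVisionEncoder",
           "BACKBONE_PRESETS"]

STRIDES = (4, 8, 16, 32)


@dataclass
class BackboneConfig:
    """Sizing of the four encoder stages."""

    embed_dims: tuple[int, ...] = (32, 64, 160, 256)
    depths: tuple[int, ...] = (2, 2, 2, 2)
    num_heads: tuple[int, ...] = (1, 2, 5, 8)
    sr_ratios: tuple[int, ...] = (8, 4, 2, 1)
    mlp_ratio: float = 4.0

    def __post_init__(self) -> None:
        for name in ("embed_dims", "depths", "num_heads", "sr_ratios"):
            if len(getattr(self, name)) != 4:
                raise ValueError(f"{name} must have length 4")
        if any(r < 1 for r in self.sr_ratios):
            raise ValueError("every sr_ratio must be >= 1")
        if any(d % h for d, h in zip(self.embed_dims, self.num_heads)):
            raise ValueError("embed_dim must be divisible by num_heads")


BACKBONE_PRESETS: dict[str, BackboneConfig] = {
    "base": BackboneConfig(),
    "tiny": BackboneConfig(embed_dims=(16, 32, 48, 64), depths=(1, 1, 1, 1),
                           num_heads=(1, 2, 4, 8), sr_ratios=(8, 4, 2, 1),
                           mlp_ratio=2.0),
}


@dataclass
class FeaturePyramid:
    """Ordered multi-scale feature maps at strides 4/8/16/32."""

    levels: list[Tensor]
    strides: tuple[int, ...] = STRIDES

    def __post_init__(self) -> None:
        if len(self.levels) != len(self.strides):
            raise ValueError("one feature map per stride required")
        if any(b <= a for a, b in zip(self.strides, self.strides[1:])):
            raise ValueError("strides must be strictly increasing")

    @property
    def channels(self) -> tuple[int, ...]:
        return tuple(l.shape[1] for l in self.levels)

    def spatial_sizes(self) -> list[tuple[int, int]]:
        return [(l.shape[2], l.shape[3]) for l in self.levels]


class OverlapPatchEmbed(Module):
    def __init__(self, in_ch: int, dim: int, kernel: int, stride: int):
        self.proj = Conv2d(in_ch, dim, kernel, stride=stride,
                           padding=kernel // 2)
        self.norm = LayerNorm(dim)

    def forward(self, x: Tensor) -> tuple[Tensor, int, int]:
        x = self.proj(x)
        _, C, H, W = x.shape
        tokens = x.reshape(x.shape[0], C, H * W).transpose(0, 2, 1)
        return self.norm(tokens), H, W

    def reset_parameters(self, rng: np.random.Generator) -> None:
        pass  # children initialise themselves


class SpatialReductionAttention(Module):
    """Multi-head self-attention with keys/values from a spatially reduced map."""

    def __init__(self, dim: int, heads: int, sr_ratio: int):
        self.dim, self.heads, self.sr_ratio = dim, heads, sr_ratio
        self.q = Linear(dim, dim)
        self.kv = Linear(dim, 2 * dim)
        self.proj = Linear(dim, dim)
        if sr_ratio > 1:
            self.sr = Conv2d(dim, dim, sr_ratio, stride=sr_ratio)
            self.sr_norm = LayerNorm(dim)

    def forward(self, x: Tensor, H: int, W: int) -> Tensor:
        N, L, C = x.shape
        h, hd = self.heads, C // self.heads
        q = self.q(x).reshape(N, L, h, hd).transpose(0, 2, 1, 3)
        if self.sr_ratio > 1:
            xm = x.transpose(0, 2, 1).reshape(N, C, H, W)
            xr = self.sr(xm)
            Lr = xr.shape[2] * xr.shape[3]
            xr = self.sr_norm(xr.reshape(N, C, Lr).transpose(0, 2, 1))
        else:
            xr, Lr = x, L
        kv = self.kv(xr).reshape(N, Lr, 2, h, hd).transpose(2, 0, 3, 1, 4)
        k, v = kv[0], kv[1]
        attn = ad.softmax((q @ k.transpose(0, 1, 3, 2)) * (hd ** -0.5), axis=-1)
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(N, L, C)
        return self.proj(out)


class MixFFN(Module):
    def __init__(self, dim: int, hidden: int):
        self.fc1 = Linear(dim, hidden)
        self.dw = Conv2d(hidden, hidden, 3, padding=1, groups=hidden)
        self.fc2 = Linear(hidden, dim)

    def forward(self, x: Tensor, H: int, W: int) -> Tensor:
        N, L, _ = x.shape
        x = self.fc1(x)
        hid = x.shape[-1]
        xm = x.transpose(0, 2, 1).reshape(N, hid, H, W)
        xm = self.dw(xm)
        x = ad.gelu(xm.reshape(N, hid, L).transpose(0, 2, 1))
        return self.fc2(x)


class EncoderBlock(Module):
    def __init__(self, dim: int, heads: int, sr_ratio: int, mlp_ratio: float):
        self.norm1 = LayerNorm(dim)
        self.attn = SpatialReductionAttention(dim, heads, sr_ratio)
        self.norm2 = LayerNorm(dim)
        self.ffn = MixFFN(dim, int(dim * mlp_ratio))

    def forward(self, x: Tensor, H: int, W: int) -> Tensor:
        x = x + self.attn(self.norm1(x), H, W)
        return x + self.ffn(self.norm2(x), H, W)


class MixVisionEncoder(Module):
    """Four-stage encoder; ``forward`` maps NCHW input to a FeaturePyramid."""

    def __init__(self, config: BackboneConfig | None = None):
        self.config = config or BackboneConfig()
        cfg = self.config
        self.embeds = ModuleList()
        self.stages = ModuleList()
        self.norms = ModuleList()
        in_ch = 3
        for i in range(4):
            kernel, stride = (7, 4) if i == 0 else (3, 2)
            self.embeds.append(OverlapPatchEmbed(in_ch, cfg.embed_dims[i],
                                                 kernel, stride))
            blocks = ModuleList(
                EncoderBlock(cfg.embed_dims[i], cfg.num_heads[i],
                             cfg.sr_ratios[i], cfg.mlp_ratio)
                for _ in range(cfg.depths[i]))
            self.stages.append(_BlockSeq(blocks))
            self.norms.append(LayerNorm(cfg.embed_dims[i]))
            in_ch = cfg.embed_dims[i]

    def forward(self, x: Tensor) -> FeaturePyramid:
        if x.ndim != 4 or x.shape[1] != 3:
            raise ValueError("expected NCHW input with 3 channels")
        H, W = x.shape[2], x.shape[3]
        if H < 32 or W < 32:
            raise ValueError("spatial size must be at least 32x32")
        if H % 32 or W % 32:
            raise ValueError("spatial size must be divisible by 32; "
                             "pad the input first (see model.pad_to_stride)")
        levels = []
        for embed, stage, norm in zip(self.embeds, self.stages, self.norms):
            x, h, w = embed(x)
            x = stage(x, h, w)
            x = norm(x)
            N, L, C = x.shape
            x = x.transpose(0, 2, 1).reshape(N, C, h, w)
            levels.append(x)
        return FeaturePyramid(levels)


class _BlockSeq(Module):
    def __init__(self, blocks: ModuleList):
        self.blocks = blocks

    def forward(self, x: Tensor, H: int, W: int) -> Tensor:
        for blk in self.blocks:
            x = blk(x, H, W)
        return x
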