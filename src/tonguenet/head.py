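"""Prediction head with per-level multi-dilation (MDi) expansion.

Each pyramid level is projected to a common width by a 1×1 convolution and
bilinearly upsampled to the stride-4 grid (the finest level), giving Z_i.
The MDi block then passes Z_i through m parallel dilated 3×3 convolutions
(rates strictly increasing, rate-matched padding so resolution is kept),
yielding m+1 maps — the m branch outputs plus the original input — which
are concatenated and fused by a 1×1 convolution with activation:

    Z = sigma(W_f * concat(Z_i, Z_{i,1}, ..., Z_{i,m}) + b_f)

The four fused level maps are concatenated, fused again by 1×1 convolution,
classified per pixel, and bilinearly upsampled to the input resolution.
With the MDi block disabled the head reduces to a plain all-MLP decoder.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import autodiff as ad
from .autodiff import Tensor, bilinear_resize, cat
from .backbone import FeaturePyramid
from .nn import BatchNorm2d, Conv2d, Module, ModuleList

__all__ = ["MDiConfig", "HeadConfig", "MDiBlock", "SegmentationHead"]


@dataclass
class MDiConfig:
    """Multi-dilation expansion: m branch rates plus the identity map."""

    m: int = 3
    rates: tuple[int, ...] = (1, 2, 4)
    activation: str = "relu"

    def __post_init__(self) -> None:
        if self.m != len(self.rates):
            raise ValueError("m must equal len(rates)")
        if self.m and (self.rates[0] < 1 or
                       any(b <= a for a, b in zip(self.rates, self.rates[1:]))):
            raise ValueError("rates must be strictly increasing and >= 1")


@dataclass
class HeadConfig:
    embed_channels: int = 256
    num_classes: int = 2
    fusion_stride: int = 4

    def __post_init__(self) -> None:
        if self.num_classes < 2:
            raise ValueError("num_classes must be >= 2")


class MDiBlock(Module):
    """m dilated 3×3 branches + identity, concatenated and 1×1-fused."""

    def __init__(self, channels: int, config: MDiConfig | None = None):
        self.config = config or MDiConfig()
        self.channels = channels
        self.branches = ModuleList(
            Conv2d(channels, channels, 3, padding=d, dilation=d)
            for d in self.config.rates)
        self.fuse = Conv2d((self.config.m + 1) * channels, channels, 1)

    def expand(self, z: Tensor) -> list[Tensor]:
        """Return [Z_i, Z_{i,1}, ..., Z_{i,m}]; all maps keep z's size."""
        return [z] + [branch(z) for branch in self.branches]

    def fuse_maps(self, maps: list[Tensor]) -> Tensor:
        if len(maps) != self.config.m + 1:
            raise ValueError(f"expected {self.config.m + 1} maps, got {len(maps)}")
        sizes = {m.shape[2:] for m in maps}
        if len(sizes) != 1:
            raise ValueError("all maps must share spatial dimensions")
        z = self.fuse(cat(maps, axis=1))
        if self.config.activation == "relu":
            z = z.relu()
        elif self.config.activation == "gelu":
            z = ad.gelu(z)
        return z

    def forward(self, z: Tensor) -> Tensor:
        return self.fuse_maps(self.expand(z))


class SegmentationHead(Module):
    """All-MLP decoder with optional per-level MDi expansion."""

    def __init__(self, in_channels: tuple[int, ...],
                 head: HeadConfig | None = None,
                 mdi: MDiConfig | None = None,
                 use_mdi: bool = True):
        self.head_config = head or HeadConfig()
        self.use_mdi = use_mdi
        cfg = self.head_config
        self.projs = ModuleList(Conv2d(c, cfg.embed_channels, 1)
                                for c in in_channels)
        if use_mdi:
            self.mdi = ModuleList(MDiBlock(cfg.embed_channels, mdi)
                                  for _ in in_channels)
        self.fuse = Conv2d(len(in_channels) * cfg.embed_channels,
                           cfg.embed_channels, 1)
        self.fuse_norm = BatchNorm2d(cfg.embed_channels)
        self.classifier = Conv2d(cfg.embed_channels, cfg.num_classes, 1)

    def forward(self, pyramid: FeaturePyramid,
                input_size: tuple[int, int]) -> Tensor:
        H, W = input_size
        s = self.head_config.fusion_stride
        h4, w4 = pyramid.levels[0].shape[2], pyramid.levels[0].shape[3]
        if (h4 * pyramid.strides[0], w4 * pyramid.strides[0]) != (H, W):
            raise ValueError("input_size inconsistent with pyramid strides")
        target = (H // s, W // s)
        fused_levels = []
        for i, (proj, level) in enumerate(zip(self.projs, pyramid.levels)):
            z = bilinear_resize(proj(level), target)
            if self.use_mdi:
                z = self.mdi[i](z)
            fused_levels.append(z)
        x = self.fuse(cat(fused_levels, axis=1))
        x = self.fuse_norm(x).relu()
        logits = self.classifier(x)
        return bilinear_resize(logits, (H, W))
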