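"""Dilated feature pyramid (DiFP) neck.

A feature-pyramid-network-style top-down fusion in which every post-merge
3×3 convolution is *dilated* with rate-matched padding, so the receptive
field grows — (k−1)·d + 1 pixels for kernel k and rate d — while the
spatial resolution of every level is preserved exactly:

    Ho = ⌊(Hi + 2p − (k−1)·d − 1)/s⌋ + 1 = Hi   when p = d, k = 3, s = 1.

The four pyramid levels use dilation rates (1, 2, 4, 6) by default, one
rate per level, increasing towards the coarser levels. Because dilation
only spaces out the kernel taps, a dilated 3×3 convolution has exactly the
same parameter count as a standard one.
"""

from __future__ import annotations

from dataclasses import dataclass

from .autodiff import upsample_nearest2x
from .backbone import FeaturePyramid
from .nn import BatchNorm2d, Conv2d, Module, ModuleList

__all__ = ["DilatedConvSpec", "NeckConfig", "receptive_field",
           "dilated_conv_shape", "DiFPNeck"]


def receptive_field(k: int, d: int) -> int:
    """Receptive-field width of a single dilated convolution.

    A kernel of size ``k`` with dilation ``d`` covers ``(k-1)*d + 1``
    input pixels along each axis.
    """
    if k < 1 or d < 1:
        raise ValueError("kernel size and dilation must be positive")
    return (k - 1) * d + 1


@dataclass
class DilatedConvSpec:
    """Geometry of one dilated convolution: kernel, rate, padding, stride."""

    Hi: int
    Wi: int
    k: int = 3
    d: int = 1
    p: int = 0
    s: int = 1

    def __post_init__(self) -> None:
        if min(self.Hi, self.Wi, self.k, self.d, self.s) < 1 or self.p < 0:
            raise ValueError("all sizes must be positive (padding >= 0)")

    def output_shape(self) -> tuple[int, int]:
        return dilated_conv_shape(self)


def dilated_conv_shape(spec: DilatedConvSpec) -> tuple[int, int]:
    """Output spatial size of a dilated convolution.

    With rate-matched padding (p = d) at k = 3, s = 1 the output equals
    the input size — the identity the neck relies on.
    """
    ext = (spec.k - 1) * spec.d  # effective extent minus one
    Ho = (spec.Hi + 2 * spec.p - ext - 1) // spec.s + 1
    Wo = (spec.Wi + 2 * spec.p - ext - 1) // spec.s + 1
    if Ho <= 0 or Wo <= 0:
        raise ValueError(f"non-positive output size {(Ho, Wo)}")
    return Ho, Wo


@dataclass
class NeckConfig:
    out_channels: int = 256
    dilation_per_level: tuple[int, ...] = (1, 2, 4, 6)

    def __post_init__(self) -> None:
        if len(self.dilation_per_level) != 4:
            raise ValueError("need one dilation rate per pyramid level")
        if any(d < 1 for d in self.dilation_per_level):
            raise ValueError("dilation rates must be >= 1")


class DiFPNeck(Module):
    """Top-down pyramid fusion with dilated output convolutions.

    Per level: a 1×1 lateral projection to a common width; top-down
    2× nearest-neighbour upsampling and addition; then a dilated 3×3
    output convolution (p = d) followed by batch norm and ReLU.
    """

    def __init__(self, in_channels: tuple[int, ...],
                 config: NeckConfig | None = None):
        self.config = config or NeckConfig()
        cfg = self.config
        if len(in_channels) != 4:
            raise ValueError("expected 4 input channel widths")
        self.laterals = ModuleList(
            Conv2d(c, cfg.out_channels, 1) for c in in_channels)
        self.out_convs = ModuleList(
            Conv2d(cfg.out_channels, cfg.out_channels, 3, padding=d, dilation=d)
            for d in cfg.dilation_per_level)
        self.out_norms = ModuleList(
            BatchNorm2d(cfg.out_channels) for _ in range(4))

    def forward(self, pyramid: FeaturePyramid) -> FeaturePyramid:
        if len(pyramid.levels) != 4:
            raise ValueError("expected a 4-level pyramid")
        laterals = [lat(x) for lat, x in zip(self.laterals, pyramid.levels)]
        merged = [None] * 4
        merged[3] = laterals[3]
        for i in (2, 1, 0):  # top-down pathway
            merged[i] = laterals[i] + upsample_nearest2x(merged[i + 1])
        outs = [norm(conv(m)).relu()
                for conv, norm, m in zip(self.out_convs, self.out_norms, merged)]
        return FeaturePyramid(outs, pyramid.strides)
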