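"""Full segmentation network: encoder + optional DiFP neck + MDi head.

The two ablation switches ``use_difp`` and ``use_mdi`` generate the four
study variants: the plain encoder/MLP-decoder baseline, baseline+MDi,
baseline+DiFP, and the full model.

Images of arbitrary size are zero-padded on the bottom/right to the next
multiple of 32 (the deepest stride) before encoding and the logits are
cropped back, so predictions align with the top-left pixel of the input.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .backbone import BACKBONE_PRESETS, BackboneConfig, MixVisionEncoder
from .head import HeadConfig, MDiConfig, SegmentationHead
from .neck import DiFPNeck, NeckConfig
from .nn import Module, count_parameters

__all__ = ["ModelConfig", "GATongueNet", "pad_to_stride", "normalize_image",
           "save_checkpoint", "load_checkpoint", "MODEL_PRESETS"]

# Per-channel RGB normalisation constants (8-bit scale), fixed for
# reproducibility across training and inference.
NORM_MEAN = (123.675, 116.28, 103.53)
NORM_STD = (58.395, 57.12, 57.375)


@dataclass
class ModelConfig:
    backbone: BackboneConfig = field(default_factory=BackboneConfig)
    neck: NeckConfig = field(default_factory=NeckConfig)
    head: HeadConfig = field(default_factory=HeadConfig)
    mdi: MDiConfig = field(default_factory=MDiConfig)
    use_difp: bool = True
    use_mdi: bool = True
    init_seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        for key, typ in (("backbone", BackboneConfig), ("neck", NeckConfig),
                         ("head", HeadConfig), ("mdi", MDiConfig)):
            sub = {k: tuple(v) if isinstance(v, list) else v
                   for k, v in d[key].items()}
            d[key] = typ(**sub)
        return cls(**d)


def _preset(name: str, **overrides) -> ModelConfig:
    if name == "base":
        cfg = ModelConfig()
    elif name == "tiny":
        cfg = ModelConfig(
            backbone=BACKBONE_PRESETS["tiny"],
            neck=NeckConfig(out_channels=32),
            head=HeadConfig(embed_channels=32),
        )
    else:
        raise KeyError(name)
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


MODEL_PRESETS = _preset


def normalize_image(image: np.ndarray) -> np.ndarray:
    """HWC uint8 RGB -> CHW float32 standardized with the fixed constants."""
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an HxWx3 RGB image")
    x = image.astype(np.float32)
    x = (x - np.array(NORM_MEAN, dtype=np.float32)) / \
        np.array(NORM_STD, dtype=np.float32)
    return np.ascontiguousarray(x.transpose(2, 0, 1))


def pad_to_stride(x: np.ndarray, stride: int = 32) -> tuple[np.ndarray, tuple[int, int]]:
    """Zero-pad NCHW bottom/right to a multiple of `stride`.

    Returns the padded array and the (pad_h, pad_w) amounts so the caller
    can crop predictions back to the original size.
    """
    H, W = x.shape[2], x.shape[3]
    ph = (-H) % stride
    pw = (-W) % stride
    if ph or pw:
        x = np.pad(x, ((0, 0), (0, 0), (0, ph), (0, pw)))
    return x, (ph, pw)


class GATongueNet(Module):
    """Encoder + (optional) dilated pyramid neck + (optional) MDi head."""

    def __init__(self, config: ModelConfig | None = None):
        self.config = config or ModelConfig()
        cfg = self.config
        self.encoder = MixVisionEncoder(cfg.backbone)
        if cfg.use_difp:
            self.neck = DiFPNeck(cfg.backbone.embed_dims, cfg.neck)
            head_in = (cfg.neck.out_channels,) * 4
        else:
            head_in = cfg.backbone.embed_dims
        self.head = SegmentationHead(head_in, cfg.head, cfg.mdi,
                                     use_mdi=cfg.use_mdi)
        self.init_parameters(np.random.default_rng(cfg.init_seed))

    def forward(self, x: Tensor) -> Tensor:
        """NCHW normalized input (divisible by 32) -> NKHW logits."""
        H, W = x.shape[2], x.shape[3]
        pyramid = self.encoder(x)
        if self.config.use_difp:
            pyramid = self.neck(pyramid)
        return self.head(pyramid, (H, W))

    def predict_logits(self, image: np.ndarray) -> np.ndarray:
        """HWC uint8 image of any size -> HxWxK logits (pad/crop handled)."""
        x = normalize_image(image)[None]
        H, W = image.shape[:2]
        xp, (ph, pw) = pad_to_stride(x)
        with ad.no_grad():
            logits = self.forward(Tensor(xp)).data[0]
        return logits[:, :H, :W].transpose(1, 2, 0)

    def predict_mask(self, image: np.ndarray) -> np.ndarray:
        """HWC uint8 image -> HxW {0,1} mask via argmax over class logits."""
        logits = self.predict_logits(image)
        return np.argmax(logits, axis=-1).astype(np.uint8)

    def n_parameters(self) -> int:
        return count_parameters(self)


def save_checkpoint(model: GATongueNet, path) -> None:
    """Serialise weights + config snapshot into a single .npz file."""
    state = model.state_dict()
    state["__config__"] = np.frombuffer(
        json.dumps(model.config.to_dict()).encode(), dtype=np.uint8)
    with open(path, "wb") as fh:
        np.savez(fh, **state)


def load_checkpoint(path) -> GATongueNet:
    with np.load(path) as npz:
        cfg = ModelConfig.from_dict(
            json.loads(bytes(npz["__config__"]).decode()))
        state = {k: npz[k] for k in npz.files if k != "__config__"}
    model = GATongueNet(cfg)
    model.load_state_dict(state)
    model.eval()
    return model
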