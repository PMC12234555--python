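"""Dataset I/O, train/test splitting and the training-time augmentation suite.

Masks live on disk as single-channel PNGs with {0, 255} encoding and in
memory as {0, 1} uint8 arrays. Manifests are two-column tab-separated files
(image_path, mask_path).

The augmentation suite applies, in order: random isotropic rescaling
(factor 0.5–2.0), random cropping retaining 75% of the image area,
horizontal flipping with probability 0.5, and photometric jitter —
brightness delta in [−32, +32] (8-bit), contrast scaling in [0.5, 1.5]
about the image mean, and saturation scaling in [0.5, 1.5] in HSV space.
Geometric transforms are applied identically to image and mask (bilinear /
nearest interpolation respectively, so masks stay binary); photometric
transforms touch only the image.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
from PIL import Image
from skimage import color as _skcolor

__all__ = ["ImagePair", "AugmentConfig", "SplitSpec", "load_pair",
           "write_mask", "write_image", "augment", "split_dataset",
           "read_manifest", "write_manifest", "IDENTITY_AUGMENT"]


@dataclass
class ImagePair:
    """An RGB image and its aligned binary ground-truth mask."""

    image: np.ndarray  # H×W×3 uint8, RGB
    mask: np.ndarray   # H×W uint8 in {0,1}
    id: str = ""

    def __post_init__(self) -> None:
        if self.image.shape[:2] != self.mask.shape:
            raise ValueError("image and mask spatial dimensions differ")
        vals = np.unique(self.mask)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("mask must contain only 0 and 1")


@dataclass
class AugmentConfig:
    scale_range: tuple[float, float] = (0.5, 2.0)
    crop_area_fraction: float = 0.75
    flip_prob: float = 0.5
    brightness_delta: tuple[float, float] = (-32.0, 32.0)
    contrast_range: tuple[float, float] = (0.5, 1.5)
    saturation_range: tuple[float, float] = (0.5, 1.5)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("scale_range", "brightness_delta", "contrast_range",
                     "saturation_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} is not well-ordered")
        if not 0 <= self.flip_prob <= 1:
            raise ValueError("flip_prob must be in [0,1]")
        if not 0 < self.crop_area_fraction <= 1:
            raise ValueError("crop_area_fraction must be in (0,1]")


IDENTITY_AUGMENT = AugmentConfig(scale_range=(1.0, 1.0), crop_area_fraction=1.0,
                                 flip_prob=0.0, brightness_delta=(0.0, 0.0),
                                 contrast_range=(1.0, 1.0),
                                 saturation_range=(1.0, 1.0))


@dataclass
class SplitSpec:
    n_train: int = 270
    n_test: int = 30
    seed: int = 0


# -- I/O ----------------------------------------------------------------------

def load_pair(image_path, mask_path, id: str | None = None) -> ImagePair:
    """Read an image/mask pair; any nonzero mask pixel becomes 1."""
    img = Image.open(image_path)
    if img.mode != "RGB":
        if img.mode in ("L", "I;16", "P", "RGBA"):
            img = img.convert("RGB")
        else:
            raise ValueError(f"cannot interpret {image_path} as RGB")
    image = np.asarray(img, dtype=np.uint8)
    m = Image.open(mask_path)
    if m.mode not in ("L", "1", "P", "I;16"):
        raise ValueError(f"mask {mask_path} is not single-channel")
    mask = (np.asarray(m.convert("L")) > 0).astype(np.uint8)
    if image.shape[:2] != mask.shape:
        raise ValueError(
            f"dimension mismatch: image {image.shape[:2]} vs mask {mask.shape}")
    if id is None:
        id = os.path.splitext(os.path.basename(image_path))[0]
    return ImagePair(image=image, mask=mask, id=id)


def write_mask(mask: np.ndarray, path) -> None:
    """Write a {0,1} mask as a {0,255} single-channel PNG."""
    mask = np.asarray(mask)
    if not np.isin(np.unique(mask), (0, 1)).all():
        raise ValueError("mask must be binary {0,1}")
    Image.fromarray((mask * 255).astype(np.uint8), mode="L").save(path)


def write_image(image: np.ndarray, path) -> None:
    Image.fromarray(np.asarray(image, dtype=np.uint8), mode="RGB").save(path)


def write_manifest(rows: list[tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        for img, msk in rows:
            fh.write(f"{img}\t{msk}\n")


def read_manifest(path) -> list[tuple[str, str]]:
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            img, msk = line.split("\t")
            rows.append((img, msk))
    return rows


# -- augmentation -------------------------------------------------------------

def _resize(image: np.ndarray, size: tuple[int, int], nearest: bool) -> np.ndarray:
    h, w = size
    pil = Image.fromarray(image)
    resample = Image.NEAREST if nearest else Image.BILINEAR
    return np.asarray(pil.resize((w, h), resample=resample))


def augment(pair: ImagePair, config: AugmentConfig,
            rng: np.random.Generator) -> ImagePair:
    """One random augmentation draw, deterministic for a given generator state."""
    image, mask = pair.image, pair.mask

    # scale (isotropic, both axes)
    lo, hi = config.scale_range
    f = float(rng.uniform(lo, hi))
    if f != 1.0:
        h = max(1, round(image.shape[0] * f))
        w = max(1, round(image.shape[1] * f))
        image = _resize(image, (h, w), nearest=False)
        mask = _resize(mask, (h, w), nearest=True)

    # crop: axis-aligned rectangle with sqrt(area)-scaled sides
    if config.crop_area_fraction < 1.0:
        side = np.sqrt(config.crop_area_fraction)
        ch = max(1, round(image.shape[0] * side))
        cw = max(1, round(image.shape[1] * side))
        if ch < 1 or cw < 1:
            raise ValueError("crop would be empty")
        top = int(rng.integers(0, image.shape[0] - ch + 1))
        left = int(rng.integers(0, image.shape[1] - cw + 1))
        image = image[top:top + ch, left:left + cw]
        mask = mask[top:top + ch, left:left + cw]

    # horizontal flip
    if config.flip_prob > 0 and rng.uniform() < config.flip_prob:
        image = image[:, ::-1]
        mask = mask[:, ::-1]

    # photometric (image only)
    x = image.astype(np.float32)
    delta = float(rng.uniform(*config.brightness_delta))
    if delta != 0.0:
        x = x + delta
    c = float(rng.uniform(*config.contrast_range))
    if c != 1.0:
        x = (x - x.mean()) * c + x.mean()
    s = float(rng.uniform(*config.saturation_range))
    if s != 1.0:
        hsv = _skcolor.rgb2hsv(np.clip(x, 0, 255).astype(np.uint8))
        hsv[..., 1] = np.clip(hsv[..., 1] * s, 0, 1)
        x = _skcolor.hsv2rgb(hsv) * 255.0
    image = np.clip(np.rint(x), 0, 255).astype(np.uint8)

    return ImagePair(image=np.ascontiguousarray(image),
                     mask=np.ascontiguousarray(mask), id=pair.id)


def split_dataset(ids, spec: SplitSpec) -> tuple[list, list]:
    """Random disjoint train/test split with fixed sizes, seeded."""
    ids = list(ids)
    if len(ids) != spec.n_train + spec.n_test:
        raise ValueError(
            f"expected {spec.n_train + spec.n_test} ids, got {len(ids)}")
    perm = np.random.default_rng(spec.seed).permutation(len(ids))
    train = [ids[i] for i in perm[:spec.n_train]]
    test = [ids[i] for i in perm[spec.n_train:]]
    return train, test
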