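"""Synthetic tongue-scene generator.

Produces image/mask pairs that emulate the two acquisition regimes the
segmenter is meant to bridge:

* **A-like** — standardized capture: a centred, teardrop-shaped reddish
  tongue region on a plain background under unit illumination.
* **B-like** — in-the-wild capture: variable tongue size and position,
  cluttered or gradient backgrounds, and global illumination shifts.

The tongue is an ellipse whose lower half is vertically stretched by a
droop coefficient (a teardrop — the minimal shape family with the tongue's
up/down asymmetry), filled with a reddish hue gradient plus a sparse
lightened "coating" speckle, composited over the background, scaled by a
global illumination gain and perturbed by low-amplitude sensor noise.
Everything is deterministic per seed.

The analytic area of the teardrop is pi*a*b*(1 + droop/2), which the test
suite uses as a rasterization oracle.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
from skimage import color as _skcolor

from .data import ImagePair, write_image, write_manifest, write_mask

__all__ = ["SyntheticScene", "generate_sample", "generate_pairs",
           "generate_dataset", "draw_scene", "teardrop_area_fraction"]

PLAIN_BG = (168, 182, 191)  # light blue-grey, plain-background colour
NOISE_SD = 2.0              # 8-bit sensor-noise standard deviation


@dataclass
class SyntheticScene:
    """Generative parameters for one synthetic tongue image + mask."""

    canvas_size: tuple[int, int] = (128, 128)       # (H, W)
    tongue_center: tuple[float, float] = (0.5, 0.5)  # (row, col) fractions
    tongue_axes: tuple[float, float] = (0.28, 0.30)  # (a, b): col/row semi-axes
    droop: float = 0.2            # lower-half vertical stretch (teardrop)
    base_hue: float = 0.985       # reddish hue in [0,1) HSV
    coating_speckle_density: float = 0.05
    background_kind: str = "plain"  # plain | gradient | clutter
    illumination_gain: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.background_kind not in ("plain", "gradient", "clutter"):
            raise ValueError(f"unknown background {self.background_kind!r}")
        cy, cx = self.tongue_center
        a, b = self.tongue_axes
        if a <= 0 or b <= 0 or self.droop < 0:
            raise ValueError("axes must be positive, droop non-negative")
        if (cx - a < 0 or cx + a > 1 or cy - b < 0
                or cy + b * (1 + self.droop) > 1):
            raise ValueError("tongue shape exits the canvas")


def teardrop_area_fraction(scene: SyntheticScene) -> float:
    """Analytic mask area as a fraction of the canvas: pi*a*b*(1+droop/2)."""
    a, b = scene.tongue_axes
    return float(np.pi * a * b * (1 + scene.droop / 2))


def _rasterize_mask(scene: SyntheticScene) -> np.ndarray:
    H, W = scene.canvas_size
    cy, cx = scene.tongue_center
    a, b = scene.tongue_axes
    # pixel-centre coordinates in canvas fractions
    yy = (np.arange(H)[:, None] + 0.5) / H
    xx = (np.arange(W)[None, :] + 0.5) / W
    b_eff = np.where(yy > cy, b * (1 + scene.droop), b)
    r2 = ((xx - cx) / a) ** 2 + ((yy - cy) / b_eff) ** 2
    return (r2 <= 1.0).astype(np.uint8)


def _background(scene: SyntheticScene, rng: np.random.Generator) -> np.ndarray:
    H, W = scene.canvas_size
    if scene.background_kind == "plain":
        bg = np.broadcast_to(np.array(PLAIN_BG, np.float32), (H, W, 3)).copy()
    elif scene.background_kind == "gradient":
        c0 = rng.uniform(40, 120, 3)
        c1 = rng.uniform(140, 220, 3)
        t = np.linspace(0, 1, H)[:, None, None]
        bg = (c0 * (1 - t) + c1 * t) * np.ones((1, W, 1))
        bg = bg.astype(np.float32)
    else:  # clutter: random rectangles and circles over a random base
        bg = np.ones((H, W, 3), np.float32) * rng.uniform(30, 220, 3)
        yy, xx = np.mgrid[0:H, 0:W]
        for _ in range(12):
            col = rng.uniform(0, 255, 3)
            if rng.uniform() < 0.5:
                y0, x0 = rng.integers(0, H), rng.integers(0, W)
                hh, ww = rng.integers(H // 8, H // 2), rng.integers(W // 8, W // 2)
                bg[y0:y0 + hh, x0:x0 + ww] = col
            else:
                cy, cx = rng.integers(0, H), rng.integers(0, W)
                rad = rng.integers(min(H, W) // 10, min(H, W) // 3)
                bg[(yy - cy) ** 2 + (xx - cx) ** 2 <= rad ** 2] = col
    return bg


def _tongue_texture(scene: SyntheticScene, mask: np.ndarray,
                    rng: np.random.Generator) -> np.ndarray:
    H, W = scene.canvas_size
    cy, _ = scene.tongue_center
    b = scene.tongue_axes[1]
    yy = (np.arange(H)[:, None] + 0.5) / H
    # hue drifts slightly and value brightens from root (top) to tip (bottom)
    depth = np.clip((yy - (cy - b)) / (b * (2 + scene.droop)), 0, 1)
    hue = (scene.base_hue + 0.015 * depth) % 1.0
    sat = 0.55 - 0.10 * depth
    val = 0.70 + 0.20 * depth
    hsv = np.stack([np.broadcast_to(hue, (H, W)),
                    np.broadcast_to(sat, (H, W)),
                    np.broadcast_to(val, (H, W))], axis=-1)
    rgb = _skcolor.hsv2rgb(hsv) * 255.0
    # lightened speckle: the whitish coating on the tongue surface
    speckle = rng.uniform(size=(H, W)) < scene.coating_speckle_density
    rgb[speckle & (mask > 0)] = rgb[speckle & (mask > 0)] * 0.4 + 0.6 * 245.0
    return rgb.astype(np.float32)


def draw_scene(scene: SyntheticScene) -> tuple[np.ndarray, np.ndarray]:
    """Render one scene; returns (HxWx3 uint8 image, HxW {0,1} mask)."""
    rng = np.random.default_rng(scene.seed)
    mask = _rasterize_mask(scene)
    img = _background(scene, rng)
    fg = _tongue_texture(scene, mask, rng)
    m3 = mask[..., None].astype(np.float32)
    img = img * (1 - m3) + fg * m3
    img = img * scene.illumination_gain
    img = img + rng.normal(0.0, NOISE_SD, img.shape)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8), mask


def generate_sample(scene: SyntheticScene) -> ImagePair:
    image, mask = draw_scene(scene)
    return ImagePair(image=image, mask=mask, id=f"synth-{scene.seed}")


def _draw_domain_scene(domain: str, rng: np.random.Generator,
                       canvas: tuple[int, int]) -> SyntheticScene:
    """Draw scene parameters from the per-domain ranges (bounded rejection)."""
    for _ in range(100):
        if domain == "A":
            params = dict(
                tongue_center=(rng.uniform(0.46, 0.52), rng.uniform(0.47, 0.53)),
                tongue_axes=(rng.uniform(0.24, 0.32), rng.uniform(0.22, 0.30)),
                droop=rng.uniform(0.10, 0.25),
                base_hue=rng.uniform(0.975, 0.995),
                coating_speckle_density=rng.uniform(0.02, 0.08),
                background_kind="plain",
                illumination_gain=1.0,
            )
        elif domain == "B":
            params = dict(
                tongue_center=(rng.uniform(0.35, 0.60), rng.uniform(0.30, 0.70)),
                tongue_axes=(rng.uniform(0.12, 0.30), rng.uniform(0.10, 0.28)),
                droop=rng.uniform(0.0, 0.35),
                base_hue=rng.uniform(0.96, 1.0) % 1.0,
                coating_speckle_density=rng.uniform(0.0, 0.15),
                background_kind="clutter" if rng.uniform() < 0.7 else "gradient",
                illumination_gain=rng.uniform(0.5, 1.5),
            )
        else:
            raise ValueError("domain must be 'A' or 'B'")
        try:
            return SyntheticScene(canvas_size=canvas, seed=int(rng.integers(2**31)),
                                  **params)
        except ValueError:
            continue
    raise RuntimeError("could not draw an in-canvas scene")


def generate_pairs(n: int, domain: str = "A", seed: int = 0,
                   canvas: tuple[int, int] = (128, 128)) -> list[ImagePair]:
    """n in-memory pairs drawn from the A-like or B-like regime."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    pairs = []
    for i in range(n):
        scene = _draw_domain_scene(domain, rng, canvas)
        pair = generate_sample(scene)
        pairs.append(ImagePair(pair.image, pair.mask, id=f"{domain}{i:04d}"))
    return pairs


def generate_dataset(n: int, domain: str, out_dir, seed: int = 0,
                     canvas: tuple[int, int] = (128, 128)) -> str:
    """Write n image/mask PNG pairs plus a manifest; returns manifest path."""
    os.makedirs(out_dir, exist_ok=True)
    rows = []
    for pair in generate_pairs(n, domain, seed, canvas):
        img_path = os.path.join(out_dir, f"{pair.id}.png")
        mask_path = os.path.join(out_dir, f"{pair.id}_mask.png")
        write_image(pair.image, img_path)
        write_mask(pair.mask, mask_path)
        rows.append((img_path, mask_path))
    manifest = os.path.join(out_dir, "manifest.tsv")
    write_manifest(rows, manifest)
    return manifest
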