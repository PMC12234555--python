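"""Dataset I/O, splitting and paired augmentation behaviour."""

import numpy as np
import pytest
from PIL import Image

from tonguenet.data import (IDENTITY_AUGMENT, AugmentConfig, ImagePair,
                            SplitSpec, augment, load_pair, split_dataset,
                            write_image, write_mask)


@pytest.fixture()
def pair_on_disk(tmp_path, rng):
    image = rng.integers(0, 255, (48, 64, 3)).astype(np.uint8)
    mask = (rng.uniform(size=(48, 64)) < 0.3).astype(np.uint8)
    ip, mp = tmp_path / "img.png", tmp_path / "mask.png"
    write_image(image, ip)
    write_mask(mask, mp)
    return image, mask, ip, mp


def test_load_pair_binarizes_and_checks_dims(pair_on_disk):
    image, mask, ip, mp = pair_on_disk
    pair = load_pair(ip, mp)
    assert np.array_equal(pair.image, image)
    assert np.array_equal(pair.mask, mask)
    assert set(np.unique(pair.mask)) <= {0, 1}


def test_load_pair_rejects_dimension_mismatch(tmp_path, rng):
    write_image(rng.integers(0, 255, (48, 64, 3)).astype(np.uint8),
                tmp_path / "i.png")
    write_mask(np.zeros((32, 32), np.uint8), tmp_path / "m.png")
    with pytest.raises(ValueError, match="mismatch"):
        load_pair(tmp_path / "i.png", tmp_path / "m.png")
    with pytest.raises(FileNotFoundError):
        load_pair(tmp_path / "missing.png", tmp_path / "m.png")


def test_mask_file_uses_0_255_encoding(tmp_path):
    mask = np.eye(8, dtype=np.uint8)
    write_mask(mask, tmp_path / "m.png")
    raw = np.asarray(Image.open(tmp_path / "m.png"))
    assert set(np.unique(raw)) == {0, 255}
    with pytest.raises(ValueError, match="binary"):
        write_mask(mask * 3, tmp_path / "bad.png")


def test_mask_write_load_round_trip(tmp_path, rng):
    for i in range(20):
        mask = (rng.uniform(size=(15, 17)) < 0.4).astype(np.uint8)
        write_image(np.zeros((15, 17, 3), np.uint8), tmp_path / f"i{i}.png")
        write_mask(mask, tmp_path / f"m{i}.png")
        assert np.array_equal(load_pair(tmp_path / f"i{i}.png",
                                        tmp_path / f"m{i}.png").mask, mask)


def test_identity_augmentation_is_a_noop(rng):
    pair = ImagePair(rng.integers(0, 255, (40, 56, 3)).astype(np.uint8),
                     (rng.uniform(size=(40, 56)) < 0.5).astype(np.uint8))
    out = augment(pair, IDENTITY_AUGMENT, np.random.default_rng(0))
    assert np.array_equal(out.image, pair.image)
    assert np.array_equal(out.mask, pair.mask)


def test_flip_mirrors_image_and_mask_identically(rng):
    cfg = AugmentConfig(scale_range=(1, 1), crop_area_fraction=1.0,
                        flip_prob=1.0, brightness_delta=(0, 0),
                        contrast_range=(1, 1), saturation_range=(1, 1))
    image = rng.integers(0, 255, (20, 30, 3)).astype(np.uint8)
    mask = (rng.uniform(size=(20, 30)) < 0.5).astype(np.uint8)
    out = augment(ImagePair(image, mask), cfg, np.random.default_rng(0))
    assert np.array_equal(out.image, image[:, ::-1])
    assert np.array_equal(out.mask, mask[:, ::-1])


def test_crop_and_flip_follow_the_coordinate_grid(rng):
    """Encode source coordinates in the image channels; after augmentation
    each mask pixel must equal the mask at the source coordinate the image
    reports — the geometric transform acted identically on both."""
    h, w = 96, 120
    rows, cols = np.mgrid[0:h, 0:w]
    image = np.stack([rows % 256, cols % 256, np.zeros_like(rows)],
                     axis=-1).astype(np.uint8)
    mask = (rng.uniform(size=(h, w)) < 0.5).astype(np.uint8)
    cfg = AugmentConfig(scale_range=(1, 1), crop_area_fraction=0.75,
                        flip_prob=1.0, brightness_delta=(0, 0),
                        contrast_range=(1, 1), saturation_range=(1, 1))
    out = augment(ImagePair(image, mask), cfg, np.random.default_rng(5))
    src_r, src_c = out.image[..., 0].astype(int), out.image[..., 1].astype(int)
    assert np.array_equal(out.mask, mask[src_r, src_c])


def test_scaling_keeps_mask_binary_and_dims_equal(rng):
    cfg = AugmentConfig(crop_area_fraction=1.0, flip_prob=0.0,
                        brightness_delta=(0, 0), contrast_range=(1, 1),
                        saturation_range=(1, 1))
    pair = ImagePair(rng.integers(0, 255, (40, 40, 3)).astype(np.uint8),
                     (rng.uniform(size=(40, 40)) < 0.5).astype(np.uint8))
    for seed in range(10):
        out = augment(pair, cfg, np.random.default_rng(seed))
        assert out.image.shape[:2] == out.mask.shape
        assert set(np.unique(out.mask)) <= {0, 1}


def test_brightness_delta_is_pointwise_addition():
    cfg = AugmentConfig(scale_range=(1, 1), crop_area_fraction=1.0,
                        flip_prob=0.0, brightness_delta=(32, 32),
                        contrast_range=(1, 1), saturation_range=(1, 1))
    gray = np.full((8, 8, 3), 128, np.uint8)
    out = augment(ImagePair(gray, np.zeros((8, 8), np.uint8)), cfg,
                  np.random.default_rng(0))
    assert (out.image == 160).all()


def test_photometric_ops_leave_mask_untouched(rng):
    cfg = AugmentConfig(scale_range=(1, 1), crop_area_fraction=1.0,
                        flip_prob=0.0)
    pair = ImagePair(rng.integers(0, 255, (24, 24, 3)).astype(np.uint8),
                     (rng.uniform(size=(24, 24)) < 0.5).astype(np.uint8))
    out = augment(pair, cfg, np.random.default_rng(7))
    assert np.array_equal(out.mask, pair.mask)


def test_augment_is_deterministic_per_rng_state(rng):
    pair = ImagePair(rng.integers(0, 255, (32, 32, 3)).astype(np.uint8),
                     (rng.uniform(size=(32, 32)) < 0.5).astype(np.uint8))
    a = augment(pair, AugmentConfig(), np.random.default_rng(99))
    b = augment(pair, AugmentConfig(), np.random.default_rng(99))
    assert np.array_equal(a.image, b.image) and np.array_equal(a.mask, b.mask)


def test_split_dataset_contract():
    ids = [f"im{i}" for i in range(300)]
    spec = SplitSpec(n_train=270, n_test=30, seed=7)
    train, test = split_dataset(ids, spec)
    assert len(train) == 270 and len(test) == 30
    assert set(train).isdisjoint(test)
    assert set(train) | set(test) == set(ids)
    assert (train, test) == split_dataset(ids, spec)
    with pytest.raises(ValueError, match="expected 300"):
        split_dataset(ids[:200], spec)


def test_augment_config_validation():
    with pytest.raises(ValueError, match="well-ordered"):
        AugmentConfig(scale_range=(2.0, 0.5))
    with pytest.raises(ValueError, match="flip_prob"):
        AugmentConfig(flip_prob=1.5)


def test_image_pair_invariants(rng):
    with pytest.raises(ValueError, match="dimensions"):
        ImagePair(np.zeros((4, 4, 3), np.uint8), np.zeros((5, 5), np.uint8))
    with pytest.raises(ValueError, match="0 and 1"):
        ImagePair(np.zeros((4, 4, 3), np.uint8), np.full((4, 4), 7, np.uint8))
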