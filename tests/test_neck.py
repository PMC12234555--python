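"""Dilated-pyramid neck: receptive field, shape law, top-down fusion."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tonguenet.autodiff import Tensor, conv2d
from tonguenet.backbone import FeaturePyramid
from tonguenet.neck import (DiFPNeck, DilatedConvSpec, NeckConfig,
                            dilated_conv_shape, receptive_field)
from tonguenet.nn import Conv2d, count_parameters


def impulse_footprint(k: int, d: int, size: int = 31) -> tuple[int, int]:
    """Oracle: backprop from one output pixel of a real dilated convolution
    and measure the bounding box of the nonzero input gradient."""
    conv = Conv2d(1, 1, k, padding=(k - 1) * d // 2, dilation=d)
    conv.weight.data[...] = 1.0
    x = Tensor(np.zeros((1, 1, size, size), np.float32), requires_grad=True)
    y = conv(x)
    g = np.zeros_like(y.data)
    g[0, 0, size // 2, size // 2] = 1.0
    y.backward(g)
    rows = np.nonzero(x.grad[0, 0].any(axis=1))[0]
    cols = np.nonzero(x.grad[0, 0].any(axis=0))[0]
    return rows[-1] - rows[0] + 1, cols[-1] - cols[0] + 1


@pytest.mark.parametrize("k,d,expected", [(3, 1, 3), (3, 2, 5), (3, 4, 9),
                                          (3, 6, 13), (1, 5, 1), (5, 3, 13)])
def test_receptive_field_closed_form_and_impulse_probe(k, d, expected):
    assert receptive_field(k, d) == expected
    assert impulse_footprint(k, d) == (expected, expected)


def test_receptive_field_rejects_nonpositive_arguments():
    with pytest.raises(ValueError):
        receptive_field(0, 1)
    with pytest.raises(ValueError):
        receptive_field(3, 0)


@pytest.mark.parametrize("spec,expected", [
    (DilatedConvSpec(Hi=576, Wi=768, k=3, d=4, p=4, s=1), (576, 768)),
    (DilatedConvSpec(Hi=10, Wi=10, k=1, d=1, p=0, s=1), (10, 10)),
    (DilatedConvSpec(Hi=8, Wi=8, k=3, d=2, p=0, s=1), (4, 4)),
])
def test_dilated_conv_shape_examples(spec, expected):
    assert dilated_conv_shape(spec) == expected


def test_dilated_conv_shape_raises_on_collapse():
    with pytest.raises(ValueError, match="non-positive"):
        dilated_conv_shape(DilatedConvSpec(Hi=4, Wi=4, k=3, d=6, p=0, s=1))


@settings(deadline=None, max_examples=60)
@given(hi=st.integers(5, 40), wi=st.integers(5, 40),
       k=st.integers(1, 5), d=st.integers(1, 4),
       p=st.integers(0, 4), s=st.integers(1, 3))
def test_shape_formula_matches_placement_enumeration(hi, wi, k, d, p, s):
    """Oracle: count valid dilated-kernel placements along each padded axis."""
    ext = (k - 1) * d + 1

    def placements(n):
        return len([i for i in range(0, n + 2 * p - ext + 1, s)])

    if placements(hi) == 0 or placements(wi) == 0:
        with pytest.raises(ValueError):
            dilated_conv_shape(DilatedConvSpec(Hi=hi, Wi=wi, k=k, d=d, p=p, s=s))
        return
    spec = DilatedConvSpec(Hi=hi, Wi=wi, k=k, d=d, p=p, s=s)
    assert dilated_conv_shape(spec) == (placements(hi), placements(wi))
    # and a real convolution agrees
    x = Tensor(np.zeros((1, 1, hi, wi), np.float32))
    w = Tensor(np.zeros((1, 1, k, k), np.float32))
    out = conv2d(x, w, stride=s, padding=p, dilation=d)
    assert out.shape[2:] == dilated_conv_shape(spec)


def _pyramid(channels=(16, 32, 48, 64), base=32, batch=1, fill=None, rng=None):
    levels = []
    for i, c in enumerate(channels):
        s = base // (2 ** i)
        data = np.zeros((batch, c, s, s), np.float32) if rng is None \
            else rng.normal(size=(batch, c, s, s)).astype(np.float32)
        if fill is not None:
            data[...] = fill
        levels.append(Tensor(data))
    return FeaturePyramid(levels)


def test_fuse_preserves_resolution_and_unifies_channels(rng):
    neck = DiFPNeck((16, 32, 48, 64), NeckConfig(out_channels=24))
    out = neck.eval()(_pyramid(rng=rng))
    assert out.spatial_sizes() == [(32, 32), (16, 16), (8, 8), (4, 4)]
    assert out.channels == (24, 24, 24, 24)


def test_zero_features_and_zero_biases_give_zero_outputs():
    neck = DiFPNeck((16, 32, 48, 64), NeckConfig(out_channels=24))
    neck.init_parameters(np.random.default_rng(0))
    out = neck.eval()(_pyramid(fill=0.0))
    for level in out.levels:
        assert not level.data.any()


def test_coarse_impulse_propagates_to_all_finer_levels():
    """Top-down pathway: an impulse at the coarsest level reaches every
    finer output through lateral-sum + upsampling."""
    neck = DiFPNeck((16, 32, 48, 64), NeckConfig(out_channels=24))
    neck.init_parameters(np.random.default_rng(3))
    pyr = _pyramid()
    pyr.levels[3].data[0, 0, 2, 2] = 5.0
    out = neck.eval()(pyr)
    for level in out.levels:
        assert np.abs(level.data).max() > 0


def test_fuse_rejects_wrong_level_count():
    neck = DiFPNeck((16, 32, 48, 64))
    pyr = _pyramid()
    pyr.levels = pyr.levels[:3]
    with pytest.raises(ValueError, match="4-level"):
        neck(pyr)


def test_dilation_adds_no_parameters():
    """A dilated 3x3 conv costs exactly as many weights as a standard one."""
    for d in (2, 4, 6):
        assert count_parameters(Conv2d(24, 24, 3, padding=d, dilation=d)) == \
            count_parameters(Conv2d(24, 24, 3, padding=1))


def test_neck_config_requires_four_positive_rates():
    with pytest.raises(ValueError):
        NeckConfig(dilation_per_level=(1, 2, 4))
    with pytest.raises(ValueError):
        NeckConfig(dilation_per_level=(0, 2, 4, 6))
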