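"""Image preparation chain: projection, rotation, background subtraction,
auto-contrast, Phansalkar threshold, particle filter."""

import numpy as np
import pytest

from angioarch.preprocess import (
    Image2D,
    autocontrast_to_8bit,
    filter_small_particles,
    max_projection,
    phansalkar_mask,
    rolling_ball_subtract,
    rotate_and_crop,
)
from angioarch.synthetic import BinaryMask, ImageStack, generate_particle_mask

PX = 2.3917


def img(a):
    return Image2D(np.asarray(a, dtype=float), PX)


# --- max projection -------------------------------------------------------

def test_max_projection_examples():
    one = ImageStack(np.arange(12.0).reshape(1, 3, 4), PX, 10.0)
    assert np.array_equal(max_projection(one).pixels, one.voxels[0])
    two = ImageStack(np.stack([np.full((2, 2), 1.0), np.full((2, 2), 5.0)]),
                     PX, 10.0)
    assert np.all(max_projection(two).pixels == 5.0)
    zero = ImageStack(np.zeros((3, 2, 2)), PX, 10.0)
    assert not max_projection(zero).pixels.any()


# --- rotate and crop ------------------------------------------------------

def test_zero_angle_is_pure_centered_crop():
    a = np.arange(400 * 500, dtype=float).reshape(400, 500)
    out = rotate_and_crop(img(a), 0.0, crop_px=(300, 200))
    assert out.pixels.shape == (200, 300)
    assert np.array_equal(out.pixels, a[100:300, 100:400])


def test_crop_too_large_reports_required_size():
    with pytest.raises(ValueError, match="at least"):
        rotate_and_crop(img(np.ones((300, 300))), 45.0, crop_px=(290, 290))


def test_rotation_brings_grooves_to_reference_axis():
    # horizontal stripes = grooves at 90 deg; after correction the
    # orientation histogram peaks at 0
    from angioarch.directionality import orientation_histogram

    y = np.arange(900, dtype=float)
    stripes = 100 * (1 + np.sin(2 * np.pi * y / 12.0))[:, None] * np.ones((1, 900))
    out = rotate_and_crop(img(stripes), 90.0, crop_px=(512, 512))
    hist = orientation_histogram(out)
    assert abs(hist.argmax_center()) <= hist.bin_width


# --- rolling ball ---------------------------------------------------------

def test_constant_image_fully_removed():
    out = rolling_ball_subtract(img(np.full((200, 200), 37.0)), 50.0)
    assert out.pixels.max() <= 37.0 * 1e-6 + 1e-9


def test_narrow_line_preserved():
    a = np.zeros((200, 200))
    a[:, 100:103] = 80.0  # width 3 px << radius 50
    out = rolling_ball_subtract(img(a), 50.0)
    assert out.pixels[:, 100:103].max() == pytest.approx(80.0, rel=0.05)


def test_output_never_exceeds_input():
    rng = np.random.default_rng(0)
    a = rng.uniform(0, 100, (300, 300))
    for downscale in (None, 1):
        out = rolling_ball_subtract(img(a), 25.0, downscale=downscale)
        assert np.all(out.pixels <= a + 1e-9)
        assert np.all(out.pixels >= 0)


def test_smooth_gradient_does_not_disturb_foreground():
    rng = np.random.default_rng(1)
    base = np.zeros((300, 300))
    for _ in range(5):  # a few bright lines
        c = rng.integers(20, 280)
        base[:, c : c + 3] = 100.0
    yy, xx = np.mgrid[0:300, 0:300]
    gradient = 30.0 * (xx / 300.0) + 20.0 * (yy / 300.0)
    out_a = rolling_ball_subtract(img(base), 50.0).pixels
    out_b = rolling_ball_subtract(img(base + gradient), 50.0).pixels
    assert np.abs(out_a - out_b).max() <= 0.10 * 100.0


# --- auto-contrast --------------------------------------------------------

def test_autocontrast_maps_range_to_8bit():
    a = np.linspace(10.0, 50.0, 10000).reshape(100, 100)
    out = autocontrast_to_8bit(img(a), saturation_fraction=0.0)
    assert out.pixels.dtype == np.uint8
    assert out.pixels.min() == 0 and out.pixels.max() == 255


def test_autocontrast_constant_warns_and_zeroes():
    with pytest.warns(UserWarning, match="constant"):
        out = autocontrast_to_8bit(img(np.full((50, 50), 9.0)))
    assert not out.pixels.any()


def test_autocontrast_ramp_clips_expected_pixel_count():
    ramp = np.arange(10000, dtype=float).reshape(100, 100)
    sat = 0.007
    lo = np.quantile(ramp, sat / 2)
    hi = np.quantile(ramp, 1 - sat / 2)
    assert int((ramp < lo).sum()) == 35
    assert int((ramp > hi).sum()) == 35
    out = autocontrast_to_8bit(img(ramp), saturation_fraction=sat)
    assert (out.pixels == 0).sum() >= 35
    assert (out.pixels == 255).sum() >= 35


# --- Phansalkar -----------------------------------------------------------

def test_phansalkar_all_zero_is_background():
    mask = phansalkar_mask(img(np.zeros((64, 64))))
    assert not mask.pixels.any()


def test_phansalkar_constant_midgray_is_foreground():
    # normalized 0.5: t = 0.5 * (1 + 2 e^-5 - 0.25) ~ 0.3817 < 0.5
    mask = phansalkar_mask(img(np.full((64, 64), 127.5)))
    assert mask.pixels.all()


def _phansalkar_oracle(image8, radius, k, r, p, q):
    """Literal per-pixel formula with mirror padding and a disk window."""
    from skimage.morphology import disk

    I = image8 / 255.0
    foot = disk(radius).astype(bool)
    pad = np.pad(I, radius, mode="reflect")
    H, W = I.shape
    out = np.zeros((H, W), dtype=bool)
    for i in range(H):
        for j in range(W):
            nb = pad[i : i + 2 * radius + 1, j : j + 2 * radius + 1][foot]
            mu = nb.mean()
            sigma = nb.std()
            t = mu * (1 + p * np.exp(-q * mu) + k * (sigma / r - 1))
            out[i, j] = I[i, j] > t
    return out


def test_phansalkar_matches_bruteforce_oracle():
    rng = np.random.default_rng(42)
    for _ in range(3):
        a = rng.integers(0, 256, (64, 64)).astype(float)
        mask = phansalkar_mask(img(a))
        oracle = _phansalkar_oracle(a, 5, 0.25, 0.5, 2.0, 10.0)
        assert np.array_equal(mask.pixels, oracle)


def test_phansalkar_square_window_supported():
    a = np.random.default_rng(0).integers(0, 256, (32, 32)).astype(float)
    m1 = phansalkar_mask(img(a), window="square")
    m2 = phansalkar_mask(img(a), window="disk")
    assert m1.pixels.shape == m2.pixels.shape


# --- particle filter ------------------------------------------------------

def test_particle_filter_area_cutoff():
    # 50 px = 286 um^2 removed; 70 px = 400.5 um^2 and 100 px kept
    mask = generate_particle_mask([50, 70, 100], (256, 256), pixel_size=PX,
                                  seed=3)
    out = filter_small_particles(mask, 400.0)
    from skimage import measure

    areas = sorted(np.bincount(
        measure.label(out.pixels, connectivity=2).ravel())[1:])
    assert areas == [70, 100]


def test_particle_filter_empty_and_idempotent():
    empty = BinaryMask(np.zeros((32, 32), bool), PX)
    assert not filter_small_particles(empty).pixels.any()
    mask = generate_particle_mask([80, 120], (256, 256), pixel_size=PX, seed=1)
    once = filter_small_particles(mask)
    twice = filter_small_particles(once)
    assert np.array_equal(once.pixels, twice.pixels)


def test_particle_filter_never_adds_foreground():
    rng = np.random.default_rng(7)
    mask = BinaryMask(rng.random((128, 128)) < 0.3, PX)
    out = filter_small_particles(mask)
    assert not (out.pixels & ~mask.pixels).any()
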