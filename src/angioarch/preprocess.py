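"""Image preparation: projection, rotation/crop, background subtraction,
auto-contrast, Phansalkar local thresholding and particle filtering.

Two fixed processing paths share a common head::

    stack -> max projection -> rotate/crop -> rolling-ball subtraction
        directionality path: stops here (orientation analysis on grayscale)
        localization path:   -> auto-contrast -> 8-bit -> Phansalkar
                             -> small-particle removal -> binary mask

The defaults are the study's analysis settings: a 2400 x 2100 px crop
(5740 x 5023 um at 2.3917 um/px), rolling-ball radius 50 px, Phansalkar
radius 5 px, and removal of particles below 400 um^2.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure, morphology, restoration, transform

from .synthetic import BinaryMask, ImageStack

__all__ = [
    "Image2D",
    "BinaryMask",
    "CROP_PX",
    "max_projection",
    "rotate_and_crop",
    "rolling_ball_subtract",
    "autocontrast_to_8bit",
    "phansalkar_mask",
    "filter_small_particles",
]

CROP_PX = (2400, 2100)  # (width, height): 5740 x 5023 um


@dataclass(frozen=True)
class Image2D:
    """2-D non-negative intensity image with pixel size in um."""

    pixels: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        p = np.asarray(self.pixels)
        object.__setattr__(self, "pixels", p)
        if p.ndim != 2:
            raise ValueError("image must be 2-D")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if np.any(p < 0):
            raise ValueError("intensities must be non-negative")


def max_projection(stack: ImageStack) -> Image2D:
    """Maximum intensity projection over Z."""
    if stack.n_slices < 1:
        raise ValueError("empty stack")
    return Image2D(np.max(stack.voxels, axis=0), stack.pixel_size_xy)


def rotate_and_crop(
    image: Image2D,
    groove_angle: float,
    crop_px: tuple[int, int] = CROP_PX,
) -> Image2D:
    """Rotate so grooves lie along the 0 deg reference axis, then crop.

    ``groove_angle`` is the current groove orientation in degrees
    relative to the reference (vertical) axis, counterclockwise
    positive; the image is rotated by the opposite angle.  The crop is
    centred and must contain no out-of-bounds fill.
    """
    cw, ch = crop_px
    img = image.pixels.astype(float)
    if groove_angle % 360 != 0:
        rot = transform.rotate(img, -groove_angle, resize=True, order=1,
                               preserve_range=True)
        valid = transform.rotate(np.ones_like(img), -groove_angle, resize=True,
                                 order=1, preserve_range=True)
    else:
        rot, valid = img, np.ones_like(img)
    H, W = rot.shape
    if ch > H or cw > W:
        raise ValueError(_crop_error(image, groove_angle, crop_px))
    r0 = (H - ch) // 2
    c0 = (W - cw) // 2
    crop = rot[r0 : r0 + ch, c0 : c0 + cw]
    vcrop = valid[r0 : r0 + ch, c0 : c0 + cw]
    if vcrop.min() < 1.0 - 1e-6:
        raise ValueError(_crop_error(image, groove_angle, crop_px))
    return Image2D(np.maximum(crop, 0.0), image.pixel_size)


def _crop_error(image: Image2D, angle: float, crop_px: tuple[int, int]) -> str:
    cw, ch = crop_px
    t = math.radians(abs(angle) % 180)
    need_w = int(math.ceil(cw * abs(math.cos(t)) + ch * abs(math.sin(t)))) + 2
    need_h = int(math.ceil(cw * abs(math.sin(t)) + ch * abs(math.cos(t)))) + 2
    h, w = image.pixels.shape
    return (
        f"crop {crop_px} at {angle:g} deg exceeds the valid rotated region of a "
        f"{w} x {h} px image; input must be at least {need_w} x {need_h} px"
    )


def _imagej_shrink_factor(radius_px: float) -> int:
    """ImageJ Subtract Background shrink schedule by ball radius."""
    if radius_px <= 10:
        return 1
    if radius_px <= 30:
        return 2
    if radius_px <= 100:
        return 4
    return 8


def rolling_ball_subtract(
    image: Image2D, radius_px: float = 50.0, downscale: int | None = None
) -> Image2D:
    """Subtract the rolling-ball background estimate, clamped at zero.

    The background is the morphological envelope of a ball of the given
    radius rolled under the intensity surface (Sternberg construction).
    By default the estimate is computed on a block-minimum-reduced image
    with a proportionally reduced radius and bilinearly upsampled — the
    same shrink schedule ImageJ's Subtract Background uses (factor 4 at
    radius 50); pass ``downscale=1`` for the exact full-resolution
    construction.  The upsampled background is clamped below the image,
    so the output never exceeds the input.
    """
    if radius_px < 1:
        raise ValueError("radius_px must be >= 1")
    img = image.pixels.astype(float)
    d = _imagej_shrink_factor(radius_px) if downscale is None else int(downscale)
    if d < 1:
        raise ValueError("downscale must be >= 1")
    if d == 1:
        bg = restoration.rolling_ball(img, radius=radius_px)
    else:
        H, W = img.shape
        ph = (-H) % d
        pw = (-W) % d
        padded = np.pad(img, ((0, ph), (0, pw)), mode="edge")
        small = padded.reshape(
            padded.shape[0] // d, d, padded.shape[1] // d, d
        ).min(axis=(1, 3))
        bg_small = restoration.rolling_ball(small, radius=max(1.0, radius_px / d))
        bg = transform.resize(
            bg_small, padded.shape, order=1, anti_aliasing=False,
            preserve_range=True,
        )[:H, :W]
    bg = np.minimum(bg, img)
    return Image2D(np.clip(img - bg, 0.0, None), image.pixel_size)


def autocontrast_to_8bit(
    image: Image2D, saturation_fraction: float = 0.007
) -> Image2D:
    """Linear rescale to 8-bit, saturating a small fraction of pixels.

    The ``saturation_fraction/2`` and ``1 - saturation_fraction/2``
    intensity quantiles map to 0 and 255; intensities outside are
    clipped.  A constant image has no contrast to stretch and maps to
    all-zero with a warning.
    """
    if not 0 <= saturation_fraction < 1:
        raise ValueError("saturation_fraction must lie in [0, 1)")
    img = image.pixels.astype(float)
    lo = np.quantile(img, saturation_fraction / 2.0)
    hi = np.quantile(img, 1.0 - saturation_fraction / 2.0)
    if hi <= lo:
        warnings.warn(
            "constant image: no contrast to stretch, output is all zero",
            stacklevel=2,
        )
        return Image2D(np.zeros_like(img, dtype=np.uint8), image.pixel_size)
    scaled = np.clip((img - lo) / (hi - lo), 0.0, 1.0) * 255.0
    return Image2D(np.round(scaled).astype(np.uint8), image.pixel_size)


def phansalkar_mask(
    image8: Image2D,
    radius_px: int = 5,
    k: float = 0.25,
    r: float = 0.5,
    p: float = 2.0,
    q: float = 10.0,
    window: str = "disk",
) -> BinaryMask:
    """Phansalkar local adaptive threshold for low-contrast images.

    With intensities ``I`` normalized to [0, 1] and local mean ``mu``
    and standard deviation ``sigma`` over the window of the given
    radius::

        t = mu * (1 + p * exp(-q * mu) + k * (sigma / r - 1))

    a pixel is foreground iff ``I > t``.  Borders are mirror-padded.
    The window is a disk by default (``window="square"`` supported).
    """
    if radius_px < 1:
        raise ValueError("radius_px must be >= 1")
    img = image8.pixels.astype(float)
    if img.max() > 255 or img.min() < 0:
        raise ValueError("image must be in 8-bit range")
    I = img / 255.0
    if window == "disk":
        foot = morphology.disk(radius_px).astype(float)
    elif window == "square":
        foot = np.ones((2 * radius_px + 1, 2 * radius_px + 1))
    else:
        raise ValueError("window must be 'disk' or 'square'")
    foot /= foot.sum()
    mu = ndimage.correlate(I, foot, mode="mirror")
    ex2 = ndimage.correlate(I * I, foot, mode="mirror")
    sigma = np.sqrt(np.maximum(ex2 - mu * mu, 0.0))
    t = mu * (1.0 + p * np.exp(-q * mu) + k * (sigma / r - 1.0))
    return BinaryMask(I > t, image8.pixel_size)


def filter_small_particles(
    mask: BinaryMask, min_area_um2: float = 400.0
) -> BinaryMask:
    """Remove connected components with physical area below the cutoff.

    Components are 8-connected (thin diagonal vessel fragments must not
    fragment).  A component of area exactly the cutoff is kept (removal
    is strictly "below").  Idempotent.
    """
    labels = measure.label(mask.pixels, connectivity=2)
    if labels.max() == 0:
        return BinaryMask(mask.pixels.copy(), mask.pixel_size)
    areas_px = np.bincount(labels.ravel())
    areas_um2 = areas_px * mask.pixel_size**2
    keep = areas_um2 >= min_area_um2
    keep[0] = False  # background
    return BinaryMask(keep[labels], mask.pixel_size)
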