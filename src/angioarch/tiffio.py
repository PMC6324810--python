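"""TIFF input/output for stacks, projections and masks."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .preprocess import Image2D
from .synthetic import PIXEL_SIZE_UM, BinaryMask, ImageStack

__all__ = ["read_stack", "write_stack", "read_image", "write_image", "write_mask"]

_META_KEY = "angioarch"


def write_stack(path: str | Path, stack: ImageStack) -> None:
    """Write a multi-page TIFF with voxel spacing in the description."""
    meta = json.dumps(
        {"pixel_size_xy_um": stack.pixel_size_xy, "z_spacing_um": stack.z_spacing}
    )
    tifffile.imwrite(path, stack.voxels, description=meta)


def read_stack(
    path: str | Path,
    pixel_size_xy: float | None = None,
    z_spacing: float | None = None,
) -> ImageStack:
    """Read a multi-page TIFF; spacings come from the description when
    written by this package, else from the arguments (pixel size
    defaults to the study's 2.3917 um/px, z spacing to 10 um)."""
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        desc = tf.pages[0].description or ""
    if data.ndim == 2:
        data = data[None]
    meta = {}
    try:
        meta = json.loads(desc)
    except (json.JSONDecodeError, TypeError):
        pass
    px = pixel_size_xy or meta.get("pixel_size_xy_um") or PIXEL_SIZE_UM
    dz = z_spacing or meta.get("z_spacing_um") or 10.0
    return ImageStack(np.clip(np.asarray(data, dtype=np.float32), 0, None), px, dz)


def write_image(path: str | Path, image: Image2D) -> None:
    meta = json.dumps({"pixel_size_um": image.pixel_size})
    tifffile.imwrite(path, image.pixels, description=meta)


def read_image(path: str | Path, pixel_size: float | None = None) -> Image2D:
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        desc = tf.pages[0].description or ""
    meta = {}
    try:
        meta = json.loads(desc)
    except (json.JSONDecodeError, TypeError):
        pass
    px = pixel_size or meta.get("pixel_size_um") or PIXEL_SIZE_UM
    return Image2D(np.clip(np.asarray(data, dtype=float), 0, None), px)


def write_mask(path: str | Path, mask: BinaryMask) -> None:
    """Masks are written as 8-bit TIFF with foreground = 255."""
    meta = json.dumps({"pixel_size_um": mask.pixel_size})
    tifffile.imwrite(
        path, (mask.pixels.astype(np.uint8) * 255), description=meta
    )


def read_mask(path: str | Path, pixel_size: float | None = None) -> BinaryMask:
    img = read_image(path, pixel_size)
    return BinaryMask(img.pixels > 0, img.pixel_size)
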