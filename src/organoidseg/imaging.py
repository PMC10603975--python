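"""Image/mask data model, PNG/TIFF I/O, and crop-resize preprocessing.

Bright-field acquisitions arrive as 8- or 16-bit grayscale rasters of
arbitrary aspect (the reference acquisitions are 1088x1388 px).  Everything
downstream of this module works on a single internal representation:
float64 intensities in [0, 1], square ``side x side`` frames (250 px at
full scale), with binary masks aligned pixel-for-pixel.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import imageio.v3 as iio
import numpy as np
from skimage.transform import resize

__all__ = [
    "GrayscaleImage",
    "BinaryMask",
    "load_image",
    "load_mask",
    "save_image",
    "save_mask",
    "preprocess",
    "preprocess_mask",
]

_MIN_SIDE = 8


@dataclass(frozen=True)
class GrayscaleImage:
    """A 2-D grayscale intensity field normalized to [0, 1].

    Parameters
    ----------
    pixels : ndarray of float, shape (height, width)
        Intensities in [0, 1].
    source_bitdepth : int
        Bit depth of the file the image was loaded from (8 or 16); images
        created in memory default to 8.
    """

    pixels: np.ndarray
    source_bitdepth: int = 8

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2:
            raise ValueError(f"expected a 2-D array, got ndim={px.ndim}")
        if px.shape[0] < _MIN_SIDE or px.shape[1] < _MIN_SIDE:
            raise ValueError(f"image too small: {px.shape} (min side {_MIN_SIDE})")
        if not np.all(np.isfinite(px)):
            raise ValueError("image intensities must be finite")
        if px.min() < 0.0 or px.max() > 1.0:
            raise ValueError("image intensities must lie in [0, 1]")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class BinaryMask:
    """A foreground/background labeling aligned with an image.

    Foreground (1) marks organoid content, background (0) everything else.
    """

    labels: np.ndarray

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.ndim != 2:
            raise ValueError(f"expected a 2-D array, got ndim={lab.ndim}")
        uniq = np.unique(lab)
        if not np.isin(uniq, (0, 1)).all():
            raise ValueError(f"mask values must be in {{0, 1}}, got {uniq}")
        object.__setattr__(self, "labels", lab.astype(np.uint8))

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def foreground_fraction(self) -> float:
        return float(self.labels.mean())


def load_image(path: str | os.PathLike) -> GrayscaleImage:
    """Read a PNG/TIFF image and normalize intensities to [0, 1].

    Multi-channel inputs are collapsed to luminance by channel averaging;
    integer data are divided by the bit-depth maximum (255 or 65535).
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such image file: {path}")
    raw = iio.imread(path)
    src_dtype = raw.dtype
    if raw.ndim == 3:
        raw = raw.mean(axis=-1)
    if np.issubdtype(src_dtype, np.integer):
        bitdepth = 16 if src_dtype.itemsize >= 2 else 8
        scale = float(2**bitdepth - 1)
        pixels = raw.astype(np.float64) / scale
    else:  # float TIFF, assume already normalized
        bitdepth = 8
        pixels = np.clip(raw.astype(np.float64), 0.0, 1.0)
    return GrayscaleImage(pixels=pixels, source_bitdepth=bitdepth)


def save_image(img: GrayscaleImage | np.ndarray, path: str | os.PathLike) -> None:
    """Write an image losslessly as 8-bit PNG (or 16-bit for 16-bit sources).

    Accepts a :class:`GrayscaleImage` or an RGB uint8 array (overlays).
    Round-trips exactly with :func:`load_image` for 8-bit data.
    """
    if isinstance(img, GrayscaleImage):
        scale = 2**img.source_bitdepth - 1
        dtype = np.uint16 if img.source_bitdepth == 16 else np.uint8
        data = np.round(img.pixels * scale).astype(dtype)
    else:
        data = np.asarray(img)
        if data.dtype != np.uint8:
            raise ValueError("raw arrays must be uint8 (RGB overlay)")
    iio.imwrite(path, data, extension=os.path.splitext(str(path))[1] or ".png")


def load_mask(path: str | os.PathLike) -> BinaryMask:
    """Read a 0/255 PNG mask back into {0, 1} labels."""
    img = load_image(path)
    return BinaryMask(labels=(img.pixels >= 0.5).astype(np.uint8))


def save_mask(mask: BinaryMask, path: str | os.PathLike) -> None:
    """Write a mask as 8-bit 0/255 PNG."""
    iio.imwrite(path, (mask.labels * 255).astype(np.uint8))


def _center_square(arr: np.ndarray) -> np.ndarray:
    h, w = arr.shape[:2]
    s = min(h, w)
    top = (h - s) // 2
    left = (w - s) // 2
    return arr[top : top + s, left : left + s]


def preprocess(img: GrayscaleImage, side: int = 250) -> GrayscaleImage:
    """Map a raw acquisition to the square network input.

    Center-crops to the largest inscribed square (preserving proportions)
    then resizes to ``side x side`` with bilinear interpolation.  Identity
    on an input that is already ``side x side``.
    """
    if side < _MIN_SIDE:
        raise ValueError(f"side must be >= {_MIN_SIDE}, got {side}")
    if img.shape == (side, side):
        return img
    sq = _center_square(img.pixels)
    if sq.shape != (side, side):
        sq = resize(sq, (side, side), order=1, anti_aliasing=sq.shape[0] > side)
    return GrayscaleImage(pixels=np.clip(sq, 0.0, 1.0), source_bitdepth=img.source_bitdepth)


def preprocess_mask(mask: BinaryMask, side: int = 250) -> BinaryMask:
    """Crop/resize a mask alongside its image.

    Nearest-neighbor interpolation followed by re-thresholding at 0.5 keeps
    the labels strictly binary.
    """
    if side < _MIN_SIDE:
        raise ValueError(f"side must be >= {_MIN_SIDE}, got {side}")
    if mask.shape == (side, side):
        return mask
    sq = _center_square(mask.labels.astype(np.float64))
    if sq.shape != (side, side):
        sq = resize(sq, (side, side), order=0, anti_aliasing=False)
    return BinaryMask(labels=(sq >= 0.5).astype(np.uint8))
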