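"""Grayscale image container and I/O.

The whole toolkit operates on single-channel 2D rasters.  :class:`GrayImage`
pairs the pixel array with its nominal bit depth (needed to interpret
dynamic range, e.g. for PSNR) and an optional physical pixel pitch in
nanometers (needed to express resolution estimates in physical units).

Pixels are stored as ``float64`` internally regardless of the bit depth of
the file they came from; the bit depth is metadata about the representable
range, not the storage dtype.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .errors import InvalidImageError

#: Maximum representable intensity per supported bit depth.
MAX_INTENSITY = {8: 255.0, 16: 65535.0, 32: float(2**32 - 1)}

#: Physical pixel pitch (nm) of the SIM acquisitions the default metric
#: configuration targets.
DEFAULT_PIXEL_SIZE_NM = 32.3

MIN_SIDE = 8


@dataclass(frozen=True, eq=False)
class GrayImage:
    """A single-channel 2D intensity raster.

    Parameters
    ----------
    pixels
        2D array of non-negative, finite intensities.
    bit_depth
        One of 8, 16 or 32; declares the representable intensity range.
    pixel_size_nm
        Optional physical pixel pitch in nanometers.
    """

    pixels: np.ndarray
    bit_depth: int = 16
    pixel_size_nm: float | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        object.__setattr__(self, "pixels", px)
        if px.ndim != 2:
            raise InvalidImageError(
                f"expected a 2D single-channel image, got shape {px.shape}"
            )
        if min(px.shape) < MIN_SIDE:
            raise InvalidImageError(
                f"image must be at least {MIN_SIDE}x{MIN_SIDE}, got {px.shape}"
            )
        if not np.all(np.isfinite(px)):
            raise InvalidImageError("image contains non-finite intensities")
        if self.bit_depth not in MAX_INTENSITY:
            raise InvalidImageError(
                f"bit_depth must be one of {sorted(MAX_INTENSITY)}, got {self.bit_depth}"
            )
        if px.size and (px.min() < 0 or px.max() > MAX_INTENSITY[self.bit_depth]):
            raise InvalidImageError(
                f"intensities outside [0, {MAX_INTENSITY[self.bit_depth]:.0f}] "
                f"for bit depth {self.bit_depth}"
            )
        if self.pixel_size_nm is not None and not self.pixel_size_nm > 0:
            raise InvalidImageError("pixel_size_nm must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def max_value(self) -> float:
        """Largest representable intensity for this bit depth."""
        return MAX_INTENSITY[self.bit_depth]

    def with_pixels(self, pixels: np.ndarray) -> "GrayImage":
        return replace(self, pixels=pixels)


def as_gray_image(obj, pixel_size_nm: float | None = None) -> GrayImage:
    """Coerce a :class:`GrayImage` or bare 2D array into a :class:`GrayImage`.

    Bare arrays get their bit depth inferred from dtype: ``uint8`` maps to
    8, ``uint16`` to 16, everything else to 32.
    """
    if isinstance(obj, GrayImage):
        return obj
    arr = np.asarray(obj)
    if arr.dtype == np.uint8:
        depth = 8
    elif arr.dtype == np.uint16:
        depth = 16
    else:
        depth = 32
    return GrayImage(arr, bit_depth=depth, pixel_size_nm=pixel_size_nm)


def to_gray8(image: GrayImage) -> GrayImage:
    """Convert to 8-bit by linear min-max rescaling to [0, 255].

    An 8-bit input is returned unchanged.  Rounding is half-to-even; a
    constant image maps to all zeros (the range is degenerate, so the
    rescale has no information to preserve).
    """
    image = as_gray_image(image)
    if image.bit_depth == 8:
        return image
    px = image.pixels
    lo, hi = px.min(), px.max()
    if hi == lo:
        out = np.zeros_like(px)
    else:
        out = np.rint((px - lo) * (255.0 / (hi - lo)))
    return GrayImage(out, bit_depth=8, pixel_size_nm=image.pixel_size_nm)


def _infer_depth(arr: np.ndarray) -> int:
    if arr.dtype == np.uint8:
        return 8
    if arr.dtype == np.uint16:
        return 16
    return 32


def read_image(path, pixel_size_nm: float | None = None) -> GrayImage:
    """Read a grayscale TIFF or PNG file.

    Multi-channel images are rejected: the naturalness statistics are
    defined for grayscale images only.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        import tifffile

        arr = tifffile.imread(path)
    elif suffix == ".png":
        import imageio.v3 as iio

        arr = iio.imread(path)
    else:
        raise InvalidImageError(f"unsupported image format: {path.name}")
    arr = np.asarray(arr)
    if arr.ndim != 2:
        raise InvalidImageError(
            f"{path.name} has shape {arr.shape}; only single-channel 2D "
            "grayscale images are supported"
        )
    return GrayImage(arr, bit_depth=_infer_depth(arr), pixel_size_nm=pixel_size_nm)


def write_image(path, image: GrayImage) -> None:
    """Write a :class:`GrayImage` as TIFF or PNG at its declared bit depth."""
    path = Path(path)
    image = as_gray_image(image)
    if image.bit_depth == 8:
        arr = np.clip(np.rint(image.pixels), 0, 255).astype(np.uint8)
    elif image.bit_depth == 16:
        arr = np.clip(np.rint(image.pixels), 0, 65535).astype(np.uint16)
    else:
        arr = image.pixels.astype(np.float32)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, arr)
    elif suffix == ".png":
        if image.bit_depth == 32:
            raise InvalidImageError("PNG output supports 8- and 16-bit only")
        import imageio.v3 as iio

        iio.imwrite(path, arr)
    else:
        raise InvalidImageError(f"unsupported image format: {path.name}")
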