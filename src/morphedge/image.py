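"""8-bit grayscale image container and file I/O.

The whole pipeline operates on 2-D 8-bit grayscale images.  Anything read
from disk is normalized once, here, to that domain: multi-channel frames are
collapsed by an unweighted channel mean, wider bit depths are min-max
rescaled to [0, 255], and values are rounded half away from zero.  After
loading, every operator works on plain float arithmetic and quantizes back
to 8 bits only when an image is saved.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .exceptions import ImageIOError, ValidationError

__all__ = ["GrayImage", "load_gray", "save_gray", "round_half_away", "as_pixel_array"]

#: Smallest image side accepted anywhere in the pipeline; the 3x3
#: neighborhood features require a one-pixel interior margin.
MIN_SIDE = 3


def round_half_away(values: np.ndarray) -> np.ndarray:
    """Round to nearest integer, halves away from zero (not banker's)."""
    values = np.asarray(values, dtype=float)
    return np.sign(values) * np.floor(np.abs(values) + 0.5)


@dataclass(frozen=True)
class GrayImage:
    """A validated 2-D 8-bit grayscale image.

    Parameters
    ----------
    pixels
        2-D array of integers in [0, 255]; stored as uint8.
    """

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValidationError(f"image must be 2-D, got shape {px.shape}")
        if px.shape[0] < MIN_SIDE or px.shape[1] < MIN_SIDE:
            raise ValidationError(
                f"image must be at least {MIN_SIDE}x{MIN_SIDE}, got {px.shape}"
            )
        if px.dtype != np.uint8:
            arr = np.asarray(px, dtype=float)
            if not np.all(np.isfinite(arr)):
                raise ValidationError("image contains non-finite values")
            if arr.min() < 0 or arr.max() > 255:
                raise ValidationError("pixel values must lie in [0, 255]")
            if not np.all(arr == np.floor(arr)):
                raise ValidationError("pixel values must be integers")
            px = arr.astype(np.uint8)
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width(self) -> int:
        return int(self.pixels.shape[1])

    @property
    def shape(self) -> tuple[int, int]:
        return (self.height, self.width)

    def as_float(self) -> np.ndarray:
        """Pixels as a float64 array (the working dtype of all operators)."""
        return self.pixels.astype(np.float64)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GrayImage):
            return NotImplemented
        return np.array_equal(self.pixels, other.pixels)


def as_pixel_array(image: "GrayImage | np.ndarray") -> np.ndarray:
    """Coerce a GrayImage or bare array to a float64 pixel matrix."""
    if isinstance(image, GrayImage):
        return image.as_float()
    arr = np.asarray(image, dtype=np.float64)
    if arr.ndim != 2:
        raise ValidationError(f"expected a 2-D image, got shape {arr.shape}")
    return arr


def _normalize_to_uint8(arr: np.ndarray) -> np.ndarray:
    """Collapse channels, rescale wide dtypes, and round to 8-bit gray."""
    arr = np.asarray(arr, dtype=np.float64)
    if arr.ndim == 3:
        # RGBA: the alpha channel is not luminance
        if arr.shape[2] == 4:
            arr = arr[:, :, :3]
        arr = arr.mean(axis=2)
    if arr.ndim != 2:
        raise ValidationError(f"cannot interpret array of shape {arr.shape} as gray image")
    if arr.size == 0:
        raise ValidationError("zero-sized image")
    lo, hi = float(arr.min()), float(arr.max())
    if lo < 0.0 or hi > 255.0:
        arr = np.zeros_like(arr) if hi == lo else (arr - lo) * (255.0 / (hi - lo))
    return round_half_away(arr).clip(0, 255).astype(np.uint8)


def load_gray(path: "str | Path", format: str | None = None) -> GrayImage:
    """Read a PNG/TIFF (or single-frame monochrome DICOM) file as 8-bit gray.

    Multi-channel inputs are converted by the unweighted channel mean;
    intensities outside [0, 255] (e.g. 16-bit data) are min-max rescaled.
    Both conversions round half away from zero, once, at load.
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt in ("dcm", "dicom"):
        arr = _read_dicom(path)
    else:
        try:
            import imageio.v3 as iio

            arr = iio.imread(path)
        except FileNotFoundError:
            raise ImageIOError(f"no such image file: {path}") from None
        except Exception as exc:  # decoder errors vary by plugin
            raise ImageIOError(f"could not read image {path}: {exc}") from exc
    return GrayImage(_normalize_to_uint8(arr))


def _read_dicom(path: Path) -> np.ndarray:
    try:
        import pydicom
    except ImportError:  # pragma: no cover - optional dependency
        raise ImageIOError("DICOM support requires the optional pydicom dependency")
    try:
        ds = pydicom.dcmread(str(path))
        arr = ds.pixel_array
    except FileNotFoundError:
        raise ImageIOError(f"no such image file: {path}") from None
    except Exception as exc:
        raise ImageIOError(f"could not read DICOM {path}: {exc}") from exc
    if arr.ndim != 2:
        raise ImageIOError(f"only single-frame monochrome DICOM is supported: {path}")
    return arr


def save_gray(image: "GrayImage | np.ndarray", path: "str | Path") -> None:
    """Write an image (or nonnegative response clipped to [0,255]) losslessly.

    PNG and TIFF round-trip bit-exactly: ``load_gray(save_gray(x)) == x``.
    """
    path = Path(path)
    if not path.parent.is_dir():
        raise ImageIOError(f"directory does not exist: {path.parent}")
    if isinstance(image, GrayImage):
        px = image.pixels
    else:
        arr = np.asarray(image, dtype=np.float64)
        px = round_half_away(arr).clip(0, 255).astype(np.uint8)
    try:
        import imageio.v3 as iio

        iio.imwrite(path, px)
    except Exception as exc:
        raise ImageIOError(f"could not write image {path}: {exc}") from exc
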