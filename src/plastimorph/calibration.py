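"""Calibrated image ingestion and pre-processing.

SEM micrographs arrive as 8- or 16-bit TIFF/PNG rasters whose physical scale
lives only in the instrument's scale-bar annotation.  This module attaches an
explicit nanometres-per-pixel calibration to the luminance grid so that every
downstream metric (edge length, particle area, pore density, ...) can be
reported in physical units.  Scale bars are never parsed: the calibration is a
mandatory, user-supplied number.

Conventions
-----------
* Luminance is stored as ``uint8`` in the full 0-255 range; 16-bit input is
  linearly rescaled over the whole container range (``v * 255 / 65535``),
  never percentile-stretched, so histogram semantics are preserved.
* RGB input is collapsed with the classic luminance weights
  0.299 / 0.587 / 0.114.
* Coordinates are 0-based and row-major; regions of interest are half-open
  rectangles.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import tifffile
from PIL import Image
from scipy import ndimage as ndi

__all__ = [
    "CalibratedImage",
    "ROI",
    "load_image",
    "save_image",
    "denoise",
    "crop",
]

# ITU-R BT.601 luma weights, the field's default greyscale conversion.
_LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])


@dataclass
class CalibratedImage:
    """A 2D luminance grid with a physical pixel size.

    Parameters
    ----------
    pixels
        ``uint8`` array of shape ``(height_px, width_px)``; values in [0, 255].
    pixel_size_nm
        Edge length of one pixel in nanometres (> 0).
    """

    pixels: np.ndarray
    pixel_size_nm: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError(f"pixels must be 2D, got shape {self.pixels.shape}")
        if self.pixels.dtype != np.uint8:
            arr = self.pixels
            if np.any(arr < 0) or np.any(arr > 255):
                raise ValueError("luminance values must lie in [0, 255]")
            self.pixels = arr.astype(np.uint8)
        if not self.pixel_size_nm > 0:
            raise ValueError(f"pixel_size_nm must be positive, got {self.pixel_size_nm}")
        self.pixel_size_nm = float(self.pixel_size_nm)

    @property
    def height_px(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width_px(self) -> int:
        return int(self.pixels.shape[1])

    @property
    def pixel_size_um(self) -> float:
        return self.pixel_size_nm / 1000.0

    @property
    def physical_height_um(self) -> float:
        return self.height_px * self.pixel_size_um

    @property
    def physical_width_um(self) -> float:
        return self.width_px * self.pixel_size_um

    @property
    def physical_area_um2(self) -> float:
        return self.physical_height_um * self.physical_width_um


@dataclass(frozen=True)
class ROI:
    """Half-open rectangular region: rows ``[row0, row0+height_px)`` etc."""

    row0: int
    col0: int
    height_px: int
    width_px: int

    def __post_init__(self) -> None:
        if self.row0 < 0 or self.col0 < 0:
            raise ValueError("ROI corner must be non-negative")
        if self.height_px <= 0 or self.width_px <= 0:
            raise ValueError("ROI extent must be positive")

    def validate_for(self, img: CalibratedImage) -> None:
        if self.row0 + self.height_px > img.height_px or self.col0 + self.width_px > img.width_px:
            raise ValueError(
                f"ROI {self} exceeds image bounds "
                f"({img.height_px}x{img.width_px})"
            )

    @property
    def n_pixels(self) -> int:
        return self.height_px * self.width_px

    def area_um2(self, pixel_size_nm: float) -> float:
        p = pixel_size_nm / 1000.0
        return self.n_pixels * p * p

    def perimeter_um(self, pixel_size_nm: float) -> float:
        p = pixel_size_nm / 1000.0
        return 2.0 * (self.height_px + self.width_px) * p

    @classmethod
    def full(cls, img: CalibratedImage) -> "ROI":
        return cls(0, 0, img.height_px, img.width_px)


def _to_luminance(arr: np.ndarray) -> np.ndarray:
    """Collapse channels and rescale to uint8 [0, 255]."""
    if arr.ndim == 3:
        if arr.shape[2] > 3:
            raise ValueError(f"images with {arr.shape[2]} channels are not supported")
        if arr.shape[2] == 1:
            arr = arr[:, :, 0]
        else:
            arr = arr.astype(np.float64) @ _LUMA_WEIGHTS
    elif arr.ndim != 2:
        raise ValueError(f"expected a 2D raster, got shape {arr.shape}")

    if arr.dtype == np.uint16:
        arr = arr.astype(np.float64) * (255.0 / 65535.0)
    elif arr.dtype == np.uint8:
        return arr
    return np.clip(np.rint(arr), 0, 255).astype(np.uint8)


def load_image(path: str | os.PathLike, pixel_size_nm: float) -> CalibratedImage:
    """Read a TIFF or PNG micrograph and attach a physical pixel size.

    16-bit input is linearly mapped over the full container range to [0, 255];
    RGB input is reduced to luminance with weights 0.299/0.587/0.114.
    """
    if not pixel_size_nm > 0:
        raise ValueError(f"pixel_size_nm must be positive, got {pixel_size_nm}")
    path = os.fspath(path)
    if not os.path.exists(path):
        raise IOError(f"no such file: {path}")
    ext = os.path.splitext(path)[1].lower()
    try:
        if ext in (".tif", ".tiff"):
            arr = tifffile.imread(path)
        else:
            with Image.open(path) as im:
                arr = np.asarray(im)
    except ValueError:
        raise
    except Exception as exc:  # decoder-specific failures
        raise IOError(f"cannot decode {path}: {exc}") from exc
    return CalibratedImage(_to_luminance(arr), pixel_size_nm)


def save_image(img: CalibratedImage, path: str | os.PathLike) -> None:
    """Write 8-bit greyscale TIFF or PNG (chosen by extension)."""
    path = os.fspath(path)
    ext = os.path.splitext(path)[1].lower()
    if ext in (".tif", ".tiff"):
        tifffile.imwrite(path, img.pixels)
    else:
        Image.fromarray(img.pixels, mode="L").save(path)


def denoise(img: CalibratedImage, sigma_px: float) -> CalibratedImage:
    """Gaussian pre-filter; ``sigma_px = 0`` is a bit-identical no-op."""
    if sigma_px < 0:
        raise ValueError(f"sigma_px must be non-negative, got {sigma_px}")
    if sigma_px == 0:
        return CalibratedImage(img.pixels.copy(), img.pixel_size_nm)
    blurred = ndi.gaussian_filter(img.pixels.astype(np.float64), sigma_px)
    out = np.clip(np.rint(blurred), 0, 255).astype(np.uint8)
    return CalibratedImage(out, img.pixel_size_nm)


def crop(img: CalibratedImage, roi: ROI) -> CalibratedImage:
    """Extract a sub-image; calibration is carried over unchanged."""
    roi.validate_for(img)
    sub = img.pixels[roi.row0 : roi.row0 + roi.height_px, roi.col0 : roi.col0 + roi.width_px]
    return CalibratedImage(sub.copy(), img.pixel_size_nm)
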