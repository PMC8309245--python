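"""Normalized luminance-as-height 3D surface visualization.

Secondary-electron luminance correlates with local topography, so a smoothed,
min-max-normalized luminance grid serves as an *uncalibrated* elevation proxy
for visual inspection of surface relief.  The z axis carries no physical
units — absolute heights would require AFM or tilt-pair photogrammetry — and
for the same reason no surface-area-from-z quantity is computed anywhere in
this module.  x and y remain physically calibrated.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .calibration import CalibratedImage

__all__ = ["HeightMap", "height_map", "export_surface", "read_surface"]


@dataclass
class HeightMap:
    """Normalized elevation proxy: z in [0, 1], unitless; x/y in physical units."""

    z: np.ndarray
    pixel_size_nm: float
    smoothing_sigma_px: float

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=np.float64)
        if self.z.ndim != 2:
            raise ValueError("height map must be 2D")


def height_map(img: CalibratedImage, smoothing_sigma_px: float = 1.0) -> HeightMap:
    """Smooth (optional) and min-max normalize luminance to [0, 1].

    A constant image normalizes to all zeros by convention, so
    ``max(z) == 1`` holds exactly whenever the source has any relief.
    The map is invariant to affine rescaling of the luminance (gain/offset).
    """
    if smoothing_sigma_px < 0:
        raise ValueError("smoothing_sigma_px must be non-negative")
    f = img.pixels.astype(np.float64)
    if smoothing_sigma_px > 0:
        f = ndi.gaussian_filter(f, smoothing_sigma_px)
    lo, hi = float(f.min()), float(f.max())
    if hi == lo:
        z = np.zeros_like(f)
    else:
        z = (f - lo) / (hi - lo)
    return HeightMap(z=z, pixel_size_nm=img.pixel_size_nm, smoothing_sigma_px=smoothing_sigma_px)


def export_surface(hm: HeightMap, path: str | os.PathLike) -> None:
    """Write the height map as an OBJ triangle mesh.

    Vertices carry x/y in µm and z in normalized (unitless) elevation; the
    regular grid is split into 2·(rows−1)·(cols−1) triangles.  OBJ is plain
    text and opens in any mesh viewer.
    """
    r, c = hm.z.shape
    p_um = hm.pixel_size_nm / 1000.0
    lines = ["# plastimorph height map (z normalized, unitless; x/y in um)"]
    for i in range(r):
        y = i * p_um
        row = hm.z[i]
        for j in range(c):
            lines.append(f"v {j * p_um:.6f} {y:.6f} {row[j]:.6f}")
    # two triangles per grid cell; OBJ indices are 1-based
    for i in range(r - 1):
        for j in range(c - 1):
            a = i * c + j + 1
            b = a + 1
            d = a + c
            e = d + 1
            lines.append(f"f {a} {b} {e}")
            lines.append(f"f {a} {e} {d}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_surface(path: str | os.PathLike) -> tuple[np.ndarray, int]:
    """Parse an OBJ written by :func:`export_surface`.

    Returns the (N, 3) vertex array and the triangle count.
    """
    verts: list[list[float]] = []
    n_faces = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith("v "):
                verts.append([float(v) for v in line.split()[1:4]])
            elif line.startswith("f "):
                n_faces += 1
    return np.array(verts), n_faces
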