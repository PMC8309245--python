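"""Surface perforation metrics.

Weathering in the breaking-wave zone perforates polymer debris; the resulting
holes are settlement habitat for biofilm.  This module counts dark
perforations inside a region of interest and reports their surface density
(holes per µm²), the percentage of the analysed area they cover, and their
mean area.  The identity ``density × mean_area = fraction / 100`` holds by
construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import morphology

from .calibration import ROI, CalibratedImage, crop
from .particles import resolve_threshold

__all__ = ["PoreMetrics", "detect_pores", "pore_metrics"]


@dataclass(frozen=True)
class PoreMetrics:
    count: int
    density_per_um2: float
    area_fraction_percent: float
    mean_pore_area_um2: float


def detect_pores(
    img: CalibratedImage,
    roi: ROI | None = None,
    threshold: str | float = "triangle",
    min_area_px: int = 10,
    max_area_px: int | None = None,
    dark_pores: bool = True,
) -> np.ndarray:
    """Label pores inside the ROI as connected components in a size window.

    Pores are dark regions by default (``dark_pores=False`` inverts).  The
    default threshold is the triangle criterion, which is built for sparse
    features against one dominant background mode — a perforated substrate
    is nearly unimodal, where Otsu would split the background noise.  The
    size window defaults to [``min_area_px``, 10% of the ROI]; components
    outside it are discarded.  Pores touching the ROI boundary are retained.
    Returns a labelled mask of the ROI's shape with consecutive labels.
    """
    if roi is None:
        roi = ROI.full(img)
    roi.validate_for(img)
    if max_area_px is None:
        max_area_px = roi.n_pixels // 10
    if min_area_px > max_area_px:
        raise ValueError(
            f"min_area_px ({min_area_px}) exceeds max_area_px ({max_area_px})"
        )
    sub = crop(img, roi).pixels
    t = resolve_threshold(sub, threshold)
    fg = sub < t if dark_pores else sub > t
    labels, n = ndi.label(fg, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return labels
    sizes = np.bincount(labels.ravel())[1:]
    keep = np.flatnonzero((sizes >= min_area_px) & (sizes <= max_area_px)) + 1
    remap = np.zeros(n + 1, dtype=labels.dtype)
    remap[keep] = np.arange(1, keep.size + 1)
    return remap[labels]


def pore_metrics(pores: np.ndarray, roi: ROI, pixel_size_nm: float) -> PoreMetrics:
    """Density, covered-area fraction and mean area of a labelled pore mask."""
    if roi.n_pixels == 0:
        raise ValueError("zero-area ROI")
    if pores.shape != (roi.height_px, roi.width_px):
        raise ValueError("pore mask shape does not match ROI")
    p_um = pixel_size_nm / 1000.0
    area_roi = roi.area_um2(pixel_size_nm)
    count = int(pores.max())
    pore_px = int(np.count_nonzero(pores))
    total_pore_area = pore_px * p_um * p_um
    if count == 0:
        return PoreMetrics(0, 0.0, 0.0, 0.0)
    return PoreMetrics(
        count=count,
        density_per_um2=count / area_roi,
        area_fraction_percent=100.0 * total_pore_area / area_roi,
        mean_pore_area_um2=total_pore_area / count,
    )
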