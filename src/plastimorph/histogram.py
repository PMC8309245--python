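"""Luminance-histogram roughness profiling.

Under fixed acquisition parameters, a rougher SEM surface scatters and
accumulates electrons over a wider range of intensities, so its luminance
histogram broadens; an ideally flat surface would emit a constant signal and
collapse to a single bin.  Histogram spread is therefore a fast first-pass
ageing/roughness indicator — an ordering cue between comparably acquired
images, not an absolute roughness value.

The histogram always covers the full 0-255 range in 256 fixed bins.  Spread
is summarised by the standard deviation (headline), interquartile range
(tie-break), and Shannon entropy in bits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .calibration import ROI, CalibratedImage, crop

__all__ = ["HistogramProfile", "RoughnessComparison", "luminance_histogram", "compare_roughness"]


@dataclass(frozen=True)
class HistogramProfile:
    counts: np.ndarray            # 256 ints, sum == total_pixels
    total_pixels: int
    mean: float
    std: float
    iqr: float
    entropy_bits: float
    normalized: np.ndarray | None = None  # counts / total, display only


@dataclass(frozen=True)
class RoughnessComparison:
    """Ordering of two comparably-acquired profiles by histogram spread."""

    ordering: str  # "a_broader" | "b_broader" | "indistinguishable"
    std_a: float
    std_b: float
    iqr_a: float
    iqr_b: float
    entropy_a: float
    entropy_b: float


def _weighted_quantile(counts: np.ndarray, q: float) -> float:
    # quantile of the discrete luminance distribution given bin counts
    cum = np.cumsum(counts)
    total = cum[-1]
    target = q * total
    idx = int(np.searchsorted(cum, target, side="left"))
    return float(idx)


def luminance_histogram(
    img: CalibratedImage, roi: ROI | None = None, normalize: bool = False
) -> HistogramProfile:
    """256-bin luminance histogram of an ROI with spread statistics.

    ``normalize`` adds a display-only normalized copy; all statistics are
    computed on the raw counts.
    """
    if roi is not None:
        img = crop(img, roi)
    pix = img.pixels
    if pix.size == 0:
        raise ValueError("zero-area ROI")
    counts = np.bincount(pix.ravel(), minlength=256).astype(np.int64)
    total = int(counts.sum())
    levels = np.arange(256, dtype=np.float64)
    p = counts / total
    mean = float(np.dot(p, levels))
    var = float(np.dot(p, (levels - mean) ** 2))
    std = float(np.sqrt(var))
    iqr = _weighted_quantile(counts, 0.75) - _weighted_quantile(counts, 0.25)
    nz = p[p > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    return HistogramProfile(
        counts=counts,
        total_pixels=total,
        mean=mean,
        std=std,
        iqr=iqr,
        entropy_bits=entropy,
        normalized=(counts / total) if normalize else None,
    )


def compare_roughness(
    a: HistogramProfile,
    b: HistogramProfile,
    comparable: bool,
    std_tolerance: float = 0.5,
) -> RoughnessComparison:
    """Order two profiles by spread: std first, IQR as tie-break.

    The caller must assert ``comparable=True``, i.e. both images were
    acquired under the same apparatus parameters — the ordering is
    meaningless otherwise and the function refuses to compute it.
    Profiles whose std differs by less than ``std_tolerance`` (and whose
    IQRs are equal) are reported as indistinguishable.
    """
    if not comparable:
        raise ValueError(
            "histogram roughness can only be compared between images acquired "
            "under identical apparatus parameters; pass comparable=True to "
            "assert that this holds"
        )
    if abs(a.std - b.std) >= std_tolerance:
        ordering = "a_broader" if a.std > b.std else "b_broader"
    elif a.iqr != b.iqr:
        ordering = "a_broader" if a.iqr > b.iqr else "b_broader"
    else:
        ordering = "indistinguishable"
    return RoughnessComparison(
        ordering=ordering,
        std_a=a.std,
        std_b=b.std,
        iqr_a=a.iqr,
        iqr_b=b.iqr,
        entropy_a=a.entropy_bits,
        entropy_b=b.entropy_bits,
    )
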