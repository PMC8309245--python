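"""Repeating-texture detection and unit-cell reconstruction.

Some weathered polymer surfaces carry strikingly regular patterns — a tiling
of one basic element.  Knowing that element ("the original puzzle") and its
two periods is enough to reconstruct the whole morphology.  Periods are
estimated from the normalized autocorrelation of the mean-subtracted image,
searched independently along rows and columns: the period is the smallest
off-origin local maximum whose correlation reaches at least half of the
zero-lag value, with ties broken toward the smaller lag.  Images with no
qualifying peak are reported as aperiodic (a result, not an error).

Only axis-aligned periodicity is modelled; an oblique lattice is recovered as
its axis projections.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from skimage import filters

from .calibration import CalibratedImage

__all__ = ["TextureUnit", "estimate_period", "extract_unit", "reconstruct_pattern"]


@dataclass(frozen=True)
class TextureUnit:
    """Axis-aligned unit cell of a periodic texture.

    ``unit_template`` and the element dimensions are filled in by
    :func:`extract_unit`; :func:`estimate_period` provides the periods only.
    """

    period_rows_px: int
    period_cols_px: int
    pixel_size_nm: float
    unit_template: np.ndarray | None = None
    unit_height_um: float | None = None
    unit_width_um: float | None = None

    @property
    def period_rows_um(self) -> float:
        return self.period_rows_px * self.pixel_size_nm / 1000.0

    @property
    def period_cols_um(self) -> float:
        return self.period_cols_px * self.pixel_size_nm / 1000.0


def _axis_autocorr(x: np.ndarray, axis: int) -> np.ndarray:
    """Normalized linear autocorrelation profile along one axis.

    ``c[d]`` is the normalized cross-correlation between the image and its
    copy shifted by ``d`` pixels along ``axis`` (other axis unshifted).
    """
    if axis == 1:
        x = x.T
    n = x.shape[0]
    max_lag = n // 2
    # raw lagged products via FFT along the shifted axis, summed over the other
    m = int(2 ** np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(x, n=m, axis=0)
    r = np.fft.irfft(f * np.conj(f), n=m, axis=0)[: max_lag + 1].sum(axis=1)
    # normalization: sqrt of the energies of the two overlapping slabs
    sq = (x * x).sum(axis=1)
    cum = np.concatenate([[0.0], np.cumsum(sq)])
    lags = np.arange(max_lag + 1)
    e_head = cum[n - lags] - cum[0]     # sum over x[:n-d]
    e_tail = cum[n] - cum[lags]         # sum over x[d:]
    denom = np.sqrt(e_head * e_tail)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.where(denom > 0, r / denom, 0.0)
    return c


def _first_qualifying_peak(c: np.ndarray, min_lag: int, threshold: float = 0.5) -> int | None:
    # smallest local maximum with correlation >= threshold; ties -> smaller lag
    for d in range(max(1, min_lag), len(c) - 1):
        if c[d] >= threshold and c[d] >= c[d - 1] and c[d] >= c[d + 1]:
            return d
    return None


def estimate_period(img: CalibratedImage, min_period_px: int = 2) -> TextureUnit | None:
    """Estimate row/column periods by autocorrelation; ``None`` = aperiodic.

    Requires the image to span at least two candidate periods per axis.
    A constant image has zero variance and is aperiodic by definition.
    """
    if min_period_px < 1:
        raise ValueError("min_period_px must be positive")
    if img.height_px < 2 * min_period_px or img.width_px < 2 * min_period_px:
        raise ValueError("image must exceed twice the minimum period in both axes")
    x = img.pixels.astype(np.float64)
    x -= x.mean()
    if not np.any(x):
        return None
    pr = _first_qualifying_peak(_axis_autocorr(x, axis=0), min_period_px)
    pc = _first_qualifying_peak(_axis_autocorr(x, axis=1), min_period_px)
    if pr is None or pc is None:
        return None
    return TextureUnit(period_rows_px=pr, period_cols_px=pc, pixel_size_nm=img.pixel_size_nm)


def _contiguity_shift(occupied: np.ndarray) -> int:
    """Circular shift that makes the occupied run contiguous from index 0.

    The cell is periodic, so an element at an arbitrary phase may straddle
    the template border.  Rolling so that the longest empty circular run ends
    at the border makes the element's bounding box meaningful.
    """
    n = occupied.size
    if occupied.all() or not occupied.any():
        return 0
    empty = np.concatenate([~occupied, ~occupied])
    best_len = best_end = run = 0
    for i, v in enumerate(empty):
        run = run + 1 if v else 0
        if run > min(best_len, n - 1):
            best_len, best_end = run, i
    return -((best_end + 1) % n)


def extract_unit(img: CalibratedImage, unit: TextureUnit) -> TextureUnit:
    """Median-stack all full tiles into the unit template and measure it.

    The per-cell median is robust against adsorbed-particle outliers that a
    mean would smear into the template.  The stored template keeps the source
    alignment, so tiling it reproduces the original pattern in phase.
    Element dimensions are the in-plane bounding-box extents of the
    thresholded template, where the element is the minority-area side of an
    Otsu split (a bump occupies less than half its cell); because the element
    may straddle the cell border at an arbitrary lattice phase, the bounding
    box is measured on a circularly re-centred copy.
    """
    if unit is None:
        raise ValueError("cannot extract a unit from an aperiodic result")
    pr, pc = unit.period_rows_px, unit.period_cols_px
    n_r = img.height_px // pr
    n_c = img.width_px // pc
    if n_r < 1 or n_c < 1:
        raise ValueError("image smaller than one full period")
    tiles = img.pixels[: n_r * pr, : n_c * pc].reshape(n_r, pr, n_c, pc)
    template = np.median(tiles, axis=(0, 2))
    template_u8 = np.clip(np.rint(template), 0, 255).astype(np.uint8)

    p_um = unit.pixel_size_nm / 1000.0
    if template_u8.min() == template_u8.max():
        h_um, w_um = pr * p_um, pc * p_um
    else:
        t = filters.threshold_otsu(template_u8)
        above = template_u8 > t
        fg = above if above.sum() <= above.size / 2 else ~above
        shift = (_contiguity_shift(fg.any(axis=1)), _contiguity_shift(fg.any(axis=0)))
        fg = np.roll(fg, shift, axis=(0, 1))
        rows = np.flatnonzero(fg.any(axis=1))
        cols = np.flatnonzero(fg.any(axis=0))
        h_um = (rows[-1] - rows[0] + 1) * p_um
        w_um = (cols[-1] - cols[0] + 1) * p_um
    return replace(unit, unit_template=template_u8, unit_height_um=h_um, unit_width_um=w_um)


def reconstruct_pattern(unit: TextureUnit, rows: int, cols: int) -> np.ndarray:
    """Tile the unit template ``rows × cols`` times into a synthetic image."""
    if rows < 1 or cols < 1:
        raise ValueError("tile counts must be positive")
    if unit.unit_template is None:
        raise ValueError("unit has no template; run extract_unit first")
    return np.tile(unit.unit_template, (rows, cols))
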