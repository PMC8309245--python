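"""Edge detection, chain-code lengths, and the niche metric table."""

import math

import numpy as np
import pytest

from plastimorph import (
    CalibratedImage,
    CannyParams,
    EdgeMap,
    ROI,
    characterize_niches,
    detect_edges,
    edge_length,
    edge_metrics_for_roi,
    skeletonize_edges,
)
from plastimorph import synthetic as syn


def _chain_map(coords, shape=(128, 128), pixel_size_nm=10.0):
    mask = np.zeros(shape, dtype=bool)
    rr, cc = zip(*coords)
    mask[list(rr), list(cc)] = True
    return EdgeMap(mask, pixel_size_nm, skeletonized=True)


class TestDetect:
    def test_constant_image_has_no_edges(self):
        img = CalibratedImage(np.full((64, 64), 90, dtype=np.uint8), 10.0)
        assert detect_edges(img).mask.sum() == 0

    def test_vertical_step_yields_chain_at_the_step_column(self):
        # the gradient maximum of a symmetric step ties on the two adjacent
        # columns; thinning reduces the response to a single vertical chain
        arr = np.zeros((64, 64), dtype=np.uint8)
        arr[:, 32:] = 255
        img = CalibratedImage(arr, 10.0)
        edges = detect_edges(img, CannyParams(sigma=1.0))
        rows, cols = np.nonzero(edges.mask)
        assert np.all(np.abs(cols - 31.5) <= 1.0)  # confined to the step columns
        assert len(np.unique(rows)) >= 56  # spans (nearly) the full height
        thin = skeletonize_edges(edges).mask
        assert 56 <= thin.sum() <= 66  # a single ~64-px chain after thinning

    def test_determinism(self):
        img, _ = syn.gen_crack_field(50, 5, seed=11)
        m1 = detect_edges(img).mask
        m2 = detect_edges(img).mask
        np.testing.assert_array_equal(m1, m2)

    def test_tiny_image_rejected(self):
        img = CalibratedImage(np.zeros((2, 5), dtype=np.uint8), 10.0)
        with pytest.raises(ValueError):
            detect_edges(img)

    def test_param_validation(self):
        with pytest.raises(ValueError):
            CannyParams(sigma=0)
        with pytest.raises(ValueError):
            CannyParams(low_frac=0.3, high_frac=0.2)
        with pytest.raises(Exception):
            CannyParams().sigma = 3.0  # frozen: series-fixed discipline


class TestChainCodeLength:
    def test_empty_map_is_zero(self):
        em = EdgeMap(np.zeros((32, 32), dtype=bool), 10.0, skeletonized=True)
        assert edge_length(em) == 0.0

    def test_horizontal_chain_exact(self):
        em = _chain_map([(64, c) for c in range(10, 111)])  # 101 px
        assert edge_length(em) == pytest.approx(1.000, abs=1e-12)

    def test_diagonal_chain_exact(self):
        em = _chain_map([(10 + i, 10 + i) for i in range(101)])
        assert edge_length(em) == pytest.approx(100 * math.sqrt(2) * 0.01, abs=1e-12)

    def test_corner_diagonal_shortcut_not_counted(self):
        # L-corner: (0,0)-(0,1)-(1,1); the (0,0)-(1,1) diagonal is a shortcut
        em = _chain_map([(10, 10), (10, 11), (11, 11)])
        assert edge_length(em) == pytest.approx(2 * 0.01, abs=1e-12)

    def test_rotation_robustness_within_10_percent(self):
        # same physical segment drawn horizontally and at 45 degrees
        n = 141
        horiz = _chain_map([(64, 10 + i) for i in range(n)], shape=(200, 200))
        diag = _chain_map([(20 + i, 20 + i) for i in range(int((n - 1) / math.sqrt(2)) + 1)],
                          shape=(200, 200))
        assert edge_length(diag) == pytest.approx(edge_length(horiz), rel=0.10)


class TestRoiMetrics:
    def test_empty_roi_metrics_are_zero(self):
        em = EdgeMap(np.zeros((64, 64), dtype=bool), 10.0)
        m = edge_metrics_for_roi(em, ROI(0, 0, 64, 64))
        assert (m.total_edge_length_um, m.edge_density_um_per_um2,
                m.edge_pixel_percent, m.edge_to_perimeter_ratio) == (0, 0, 0, 0)

    def test_density_is_length_over_area(self):
        img, _ = syn.gen_crack_field(60, 6, seed=21)
        em = detect_edges(img, CannyParams(sigma=1.5))
        roi = ROI(0, 0, 256, 512)
        m = edge_metrics_for_roi(em, roi)
        assert m.edge_density_um_per_um2 == pytest.approx(
            m.total_edge_length_um / roi.area_um2(100.0), rel=1e-12)
        assert 0 <= m.edge_pixel_percent <= 100

    def test_halved_convention_halves_all_length_metrics(self):
        img, _ = syn.gen_crack_field(60, 6, seed=21)
        em = detect_edges(img, CannyParams(sigma=1.5))
        roi = ROI(0, 0, 512, 512)
        full = edge_metrics_for_roi(em, roi)
        half = edge_metrics_for_roi(em, roi, halve=True)
        assert half.total_edge_length_um == pytest.approx(full.total_edge_length_um / 2)
        assert half.edge_pixel_percent == full.edge_pixel_percent

    def test_ground_truth_recovery_two_sided_halved(self):
        """Halved two-sided response within 10% of analytic crack length."""
        img, gt = syn.gen_crack_field(120, 6, seed=31)
        em = detect_edges(img, CannyParams(sigma=1.5))
        assert edge_length(em) / 2 == pytest.approx(gt.total_length_um, rel=0.10)


class TestNicheTable:
    def test_one_row_per_roi_and_density_ordering(self):
        # two zones with crack densities d and 2d -> density ratio ~2 within 10%
        img_lo, gt_lo = syn.gen_crack_field(40, 4, seed=41, size_px=256)
        img_hi, gt_hi = syn.gen_crack_field(80, 8, seed=42, size_px=256)
        combo = np.hstack([img_lo.pixels, img_hi.pixels])
        img = CalibratedImage(combo, 100.0)
        rois = [ROI(0, 0, 256, 256), ROI(0, 256, 256, 256)]
        table = characterize_niches(img, rois, CannyParams(sigma=1.5))
        assert len(table) == 2
        ratio = (table.edge_density_um_per_um2[1] / table.edge_density_um_per_um2[0])
        truth = gt_hi.total_length_um / gt_lo.total_length_um
        assert ratio == pytest.approx(truth, rel=0.10)

    def test_blank_zone_gives_zero_row(self):
        img = CalibratedImage(np.full((64, 128), 120, dtype=np.uint8), 100.0)
        table = characterize_niches(img, [ROI(0, 0, 64, 64)])
        assert table.edge_length_um[0] == 0.0

    def test_requires_at_least_one_roi(self):
        img = CalibratedImage(np.zeros((32, 32), dtype=np.uint8), 100.0)
        with pytest.raises(ValueError):
            characterize_niches(img, [])
        with pytest.raises(ValueError):
            characterize_niches(img, [ROI(0, 0, 64, 64)])  # out of bounds


def test_skeletonized_map_consistency_identity():
    """density ~= (percent/100)/pixel_size within the [1, sqrt(2)] diagonal band."""
    img, _ = syn.gen_crack_field(80, 8, seed=51)
    em = skeletonize_edges(detect_edges(img, CannyParams(sigma=1.5)))
    roi = ROI(0, 0, 512, 512)
    m = edge_metrics_for_roi(em, roi)
    baseline = (m.edge_pixel_percent / 100.0) / (em.pixel_size_nm / 1000.0)
    factor = m.edge_density_um_per_um2 / baseline
    assert 1.0 <= factor <= math.sqrt(2)
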