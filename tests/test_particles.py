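"""Particle segmentation, grain sizes, sphere volumes, fibre morphometry."""

import math

import numpy as np
import pytest

from plastimorph import (
    CalibratedImage,
    fibre_diameters,
    fibre_mask,
    grain_size_distribution,
    inter_fibre_spacing,
    particle_stats,
    segment_particles,
    total_area_um2,
)
from plastimorph import synthetic as syn


def _disk_image(centres, radius_px, shape=(256, 256), fg=200, bg=40, pixel_size_nm=100.0):
    arr = np.full(shape, bg, dtype=np.uint8)
    rr, cc = np.indices(shape)
    for r0, c0 in centres:
        arr[(rr - r0) ** 2 + (cc - c0) ** 2 <= radius_px**2] = fg
    return CalibratedImage(arr, pixel_size_nm)


class TestSegmentation:
    def test_blank_image_has_no_labels(self):
        img = CalibratedImage(np.full((64, 64), 50, dtype=np.uint8), 100.0)
        assert segment_particles(img, threshold=120.0).max() == 0

    def test_three_disjoint_disks_three_labels(self):
        img = _disk_image([(60, 60), (60, 180), (180, 120)], 20)
        labels = segment_particles(img)
        assert labels.max() == 3

    def test_overlapping_disks_merge_into_one_label(self):
        img = _disk_image([(100, 100), (100, 125)], 20)
        assert segment_particles(img).max() == 1

    def test_min_area_filter_removes_specks(self):
        img = _disk_image([(100, 100)], 2)  # 13 px disk
        assert segment_particles(img, min_area_px=50).max() == 0
        assert segment_particles(img, min_area_px=10).max() == 1

    def test_labels_consecutive_after_filtering(self):
        img = _disk_image([(40, 40), (40, 200), (200, 40)], 15)
        small = _disk_image([(200, 200)], 2).pixels
        arr = np.maximum(img.pixels, small)
        labels = segment_particles(CalibratedImage(arr, 100.0), min_area_px=50)
        assert sorted(np.unique(labels)) == [0, 1, 2, 3]

    def test_threshold_value_validated(self):
        img = _disk_image([(50, 50)], 10)
        with pytest.raises(ValueError):
            segment_particles(img, threshold=300.0)
        with pytest.raises(ValueError):
            segment_particles(img, threshold="median")


class TestParticleStats:
    def test_disk_area_matches_analytic_circle(self):
        # r = 50 px at 100 nm/px -> 5 um; area pi*25 within 2% (rasterization)
        img = _disk_image([(128, 128)], 50)
        rec = particle_stats(segment_particles(img), 100.0)[0]
        assert rec.area_um2 == pytest.approx(math.pi * 25.0, rel=0.02)
        assert rec.equivalent_diameter_um == pytest.approx(10.0, rel=0.01)
        assert not rec.touches_border

    def test_sphere_volume_closed_form(self):
        # equivalent radius 10 um -> (4/3)*pi*1000 = 4188.7902 um^3
        img = _disk_image([(128, 128)], 100)
        rec = particle_stats(segment_particles(img), 100.0, assume_spherical=True)[0]
        r = rec.equivalent_diameter_um / 2
        assert rec.volume_um3 == pytest.approx((4 / 3) * math.pi * r**3, rel=1e-12)
        assert rec.volume_um3 == pytest.approx(4188.7902, rel=0.02)

    def test_scale_equivariance_exact(self):
        img = _disk_image([(64, 64), (180, 180)], 25)
        labels = segment_particles(img)
        a = particle_stats(labels, 100.0, assume_spherical=True)
        b = particle_stats(labels, 200.0, assume_spherical=True)
        for ra, rb in zip(a, b):
            assert rb.area_um2 == pytest.approx(4 * ra.area_um2, rel=1e-12)
            assert rb.equivalent_diameter_um == pytest.approx(
                2 * ra.equivalent_diameter_um, rel=1e-12)
            assert rb.volume_um3 == pytest.approx(8 * ra.volume_um3, rel=1e-12)

    def test_area_conservation(self):
        img, _ = syn.gen_spheres(12, (2, 6), size_px=512, pixel_size_nm=200, seed=3)
        labels = segment_particles(img)
        recs = particle_stats(labels, img.pixel_size_nm)
        p2 = (img.pixel_size_nm / 1000.0) ** 2
        assert total_area_um2(recs) == pytest.approx(np.count_nonzero(labels) * p2, rel=1e-9)

    def test_border_particle_flagged(self):
        img = _disk_image([(0, 100)], 30)
        rec = particle_stats(segment_particles(img), 100.0)[0]
        assert rec.touches_border


class TestGrainSize:
    def test_empty_records_all_zero(self):
        gsd = grain_size_distribution([], 1.0)
        assert gsd.counts.sum() == 0

    def test_monodisperse_population_in_one_bin(self):
        img = _disk_image([(40 + 60 * (i // 3), 40 + 80 * (i % 3)) for i in range(9)],
                          27, shape=(256, 256))  # equivalent diameter ~5.4 um
        recs = particle_stats(segment_particles(img), 100.0)
        gsd = grain_size_distribution(recs, 1.0)
        assert gsd.counts[5] == len(recs)
        assert gsd.counts.sum() == len(recs)

    def test_bimodal_populations_counted_separately(self):
        # two monodisperse fields placed side by side: 20 x 5.4 um, 10 x 9.4 um
        img, _ = syn.gen_spheres(20, (2.7, 2.7), size_px=512, pixel_size_nm=200, seed=5)
        img2, _ = syn.gen_spheres(10, (4.7, 4.7), size_px=512, pixel_size_nm=200, seed=6)
        arr = np.hstack([img.pixels, img2.pixels])
        recs = particle_stats(
            segment_particles(CalibratedImage(arr, 200.0)), 200.0)
        gsd = grain_size_distribution(recs, 1.0)
        assert gsd.counts[5] == 20
        assert gsd.counts[9] == 10

    def test_border_exclusion_but_total_area_keeps_them(self):
        img = _disk_image([(0, 60), (128, 128)], 25)
        recs = particle_stats(segment_particles(img), 100.0)
        gsd = grain_size_distribution(recs, 1.0)
        assert gsd.counts.sum() == 1
        assert total_area_um2(recs) > particle_stats(
            segment_particles(_disk_image([(128, 128)], 25)), 100.0)[0].area_um2

    def test_nonpositive_bin_width_rejected(self):
        with pytest.raises(ValueError):
            grain_size_distribution([], 0.0)


class TestFibres:
    def test_blank_image_empty_stats(self):
        img = CalibratedImage(np.full((64, 64), 30, dtype=np.uint8), 100.0)
        stats = fibre_diameters(img, threshold=128.0)
        assert stats.diameter_samples_um.size == 0
        assert stats.modal_diameters_um == []

    def test_straight_fibre_width_95px_modal_9p5um(self):
        arr = np.full((256, 256), 40, dtype=np.uint8)
        arr[80:175, :] = 220  # 95 rows wide, axis-aligned
        stats = fibre_diameters(CalibratedImage(arr, 100.0))
        assert stats.modal_diameters_um[0] == pytest.approx(9.5, abs=0.1)

    def test_two_population_mesh_recovers_both_widths(self):
        img, _ = syn.gen_fibre_mesh(4, [9.5, 5.0], size_px=512, pixel_size_nm=100,
                                    seed=7, spacing_target_um=8.0)
        stats = fibre_diameters(img)
        top2 = sorted(stats.modal_diameters_um[:2], reverse=True)
        assert top2[0] == pytest.approx(9.5, abs=0.1)
        assert top2[1] == pytest.approx(5.0, abs=0.1)

    def test_parallel_fibre_gap_recovered(self):
        # two vertical fibres with a 100-px surface gap at 100 nm/px -> 10 um
        arr = np.full((256, 256), 40, dtype=np.uint8)
        arr[:, 50:70] = 220
        arr[:, 170:190] = 220
        sp = inter_fibre_spacing(fibre_mask(CalibratedImage(arr, 100.0)), 100.0)
        interior = sp.spacing_samples_um[
            (sp.spacing_samples_um > 5) & (sp.spacing_samples_um < 15)]
        assert np.median(interior) == pytest.approx(10.0, abs=0.1)

    def test_all_foreground_mask_empty_distribution(self):
        sp = inter_fibre_spacing(np.ones((32, 32), dtype=bool), 100.0)
        assert sp.spacing_samples_um.size == 0

    def test_single_fibre_flagged_boundary_dominated(self):
        arr = np.full((256, 256), 40, dtype=np.uint8)
        arr[120:140, :] = 220
        sp = inter_fibre_spacing(fibre_mask(CalibratedImage(arr, 100.0)), 100.0)
        assert sp.boundary_dominated
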