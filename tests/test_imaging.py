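"""Larval-detection algorithm: grid location, empty-well background
estimation, difference segmentation and the high-background flag."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from larvascreen import imaging
from larvascreen.simulate import LarvaSpec, render_larva, stamp_larva

from conftest import GEOMETRY, GRID, uniform_well_patch


def _add_blob(patch, cy, cx, sigma=12.0, depth=0.2):
    yy, xx = np.mgrid[:patch.shape[0], :patch.shape[1]]
    patch -= depth * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma ** 2))
    return patch


class TestLocateWellGrid:
    def test_centers_recovered_within_two_pixels(self, clean_plate):
        img, truth = clean_plate
        regions = imaging.locate_well_grid(img, GRID)
        assert len(regions) == 96
        cents = {(r.row, r.col): r.center for r in regions}
        for rec in truth.itertuples(index=False):
            cy, cx = cents[(rec.row, rec.col)]
            assert abs(cy - rec.center_y) <= 2 and abs(cx - rec.center_x) <= 2

    def test_translation_shifts_all_centers(self, clean_plate):
        img, truth = clean_plate
        dy, dx = 14, 21
        padded = np.pad(img, ((dy, 0), (dx, 0)), mode="edge")
        cents = {(r.row, r.col): r.center
                 for r in imaging.locate_well_grid(padded, GRID)}
        for rec in truth.itertuples(index=False):
            cy, cx = cents[(rec.row, rec.col)]
            assert abs(cy - (rec.center_y + dy)) <= 2
            assert abs(cx - (rec.center_x + dx)) <= 2

    def test_blank_image_raises(self):
        blank = np.random.default_rng(0).normal(0.75, 0.01, GEOMETRY.image_shape)
        with pytest.raises(ValueError, match="no well grid"):
            imaging.locate_well_grid(blank, GRID)

    def test_too_small_image_raises(self):
        with pytest.raises(ValueError, match="smaller"):
            imaging.locate_well_grid(np.zeros((200, 200)), GRID)


class TestEstimateEmptyBackground:
    def test_uniform_well_estimate_equals_input(self):
        patch = uniform_well_patch(0.75)
        bg = imaging.estimate_empty_background(patch)
        assert np.abs(bg.estimate - patch).max() < 1 / 255
        assert bg.residual_metric < 1e-6

    def test_constant_background_recovered_under_blob(self):
        patch = uniform_well_patch(0.8)
        _add_blob(patch, 65, 65, sigma=8, depth=0.3)
        bg = imaging.estimate_empty_background(patch)
        under = np.hypot(*(np.mgrid[:131, :131] - 65)) < 16
        assert np.abs(bg.estimate[under] - 0.8).max() < 0.02

    def test_linear_ramp_recovered_under_blob(self):
        patch = uniform_well_patch(0.0)
        yy, xx = np.mgrid[:131, :131]
        ramp = 0.6 + 0.2 * xx / 130 + 0.1 * yy / 130  # range 0.3 over the patch
        patch += ramp
        _add_blob(patch, 60, 70, sigma=9, depth=0.3)
        bg = imaging.estimate_empty_background(patch)
        under = np.hypot(yy - 60, xx - 70) < 18
        assert np.abs((bg.estimate - ramp)[under]).max() < 0.03 * 0.3

    def test_idempotent_on_its_own_estimate(self):
        patch = uniform_well_patch(0.75, noise=0.008, seed=3)
        cy, cx = 65, 65
        larva = render_larva(LarvaSpec(26, 6, 0.2, position=(cy - 15, cx)))
        stamp_larva(patch, larva, background_level=0.75)
        est1 = imaging.estimate_empty_background(patch).estimate
        est2 = imaging.estimate_empty_background(est1).estimate
        assert np.abs(est2 - est1).max() < 1 / 255

    def test_total_exclusion_raises(self):
        # dark debris scattered densely enough that the dilated exclusion
        # swallows the whole interior leaves nothing to interpolate from
        patch = uniform_well_patch(0.75, noise=0.005, seed=9)
        rng = np.random.default_rng(10)
        salt = rng.uniform(size=patch.shape) < 0.2
        patch[salt] = 0.1
        with pytest.raises(ValueError, match="cannot interpolate"):
            imaging.estimate_empty_background(patch, edge_margin=6)


class TestDetectLarvae:
    def test_zero_difference_well_has_no_components(self):
        patch = uniform_well_patch(0.75)
        bg = imaging.estimate_empty_background(patch)
        m = imaging.detect_larvae(patch, bg, diff_threshold=0.05)
        assert m.n_components == 0 and m.total_area == 0

    def test_single_larva_area_within_ten_percent(self):
        patch = uniform_well_patch(0.75, noise=0.008, seed=1)
        larva = render_larva(LarvaSpec(32, 7.5, 0.25, position=(60.3, 70.2),
                                       orientation=0.7))
        stamp_larva(patch, larva, background_level=0.75)
        bg = imaging.estimate_empty_background(patch)
        m = imaging.detect_larvae(patch, bg)
        assert m.n_components == 1
        assert abs(m.total_area - larva.area) / larva.area < 0.10

    def test_three_disjoint_larvae_counted_and_measured(self):
        patch = uniform_well_patch(0.75, noise=0.008, seed=2)
        specs = [LarvaSpec(28, 6.5, 0.1, position=(40, 65), orientation=0.2),
                 LarvaSpec(30, 7.0, 0.2, position=(88, 55), orientation=1.5),
                 LarvaSpec(26, 6.0, 0.3, position=(66, 95), orientation=2.4)]
        total = 0
        for s in specs:
            r = render_larva(s)
            stamp_larva(patch, r, background_level=0.75)
            total += r.area
        bg = imaging.estimate_empty_background(patch)
        m = imaging.detect_larvae(patch, bg)
        assert m.n_components == 3
        assert abs(m.total_area - total) / total < 0.10
        assert m.total_area == sum(c["area"] for c in m.components)

    def test_nonpositive_threshold_rejected(self):
        patch = uniform_well_patch(0.75)
        bg = imaging.estimate_empty_background(patch)
        with pytest.raises(ValueError):
            imaging.detect_larvae(patch, bg, diff_threshold=0.0)

    def test_scale_equivariance(self):
        patch = uniform_well_patch(0.75, noise=0.008, seed=4)
        larva = render_larva(LarvaSpec(30, 7, 0.2, position=(65.4, 64.8)))
        stamp_larva(patch, larva, background_level=0.75)
        m1 = imaging.detect_larvae(patch, imaging.estimate_empty_background(patch),
                                   diff_threshold=0.06)
        c = 3.7
        m2 = imaging.detect_larvae(c * patch,
                                   imaging.estimate_empty_background(c * patch),
                                   diff_threshold=c * 0.06)
        assert m1.total_area == m2.total_area
        assert m1.n_components == m2.n_components


class TestHighBackgroundFlag:
    def test_clean_wells_rarely_flagged_and_blob_wells_flagged(
            self, clean_measurements, artifact_plate):
        clean_resid = clean_measurements["residual_metric"]
        cutoff = imaging.clean_residual_cutoff(clean_resid)
        n_false = int((clean_resid > cutoff).sum())
        assert n_false <= int(np.ceil(0.01 * len(clean_resid)))

        img, truth = artifact_plate
        meas = imaging.measure_plate(img, GRID)
        m = meas.merge(truth[["row", "col", "flag_high_bg"]], on=["row", "col"])
        blob = m[m["flag_high_bg"]]
        assert len(blob) > 20
        assert blob["residual_metric"].gt(cutoff).mean() >= 0.95

    def test_residual_exactly_at_cutoff_is_not_flagged(self):
        m = imaging.WellMeasurement("A1", 0, 0, residual_metric=0.5)
        assert imaging.flag_high_background(m, residual_cutoff=0.5) is False
        assert imaging.flag_high_background(m, residual_cutoff=0.49) is True


class TestImageIO:
    def test_tiff_round_trip_preserves_detections(self, clean_plate, tmp_path):
        img, _ = clean_plate
        path = tmp_path / "plate.tif"
        imaging.write_plate_image(path, img)
        back = imaging.read_plate_image(path)
        assert back.shape == img.shape
        assert np.abs(back - np.clip(img, 0, 1)).max() < 1e-4  # 16-bit depth
        regions = imaging.locate_well_grid(back, GRID)
        assert len(regions) == 96


class TestOracleEquivalence:
    def test_detected_areas_track_ground_truth(self, clean_measurements):
        m = clean_measurements[clean_measurements["true_area"] > 0]
        rel = np.abs(m["total_area_px"] - m["true_area"]) / m["true_area"]
        assert np.median(rel) <= 0.10
        assert spearmanr(m["total_area_px"], m["true_area"]).statistic >= 0.95

    def test_area_conservation_bounds(self, clean_measurements):
        well_px = np.pi * (0.95 * GEOMETRY.well_radius) ** 2
        assert (clean_measurements["total_area_px"] <= well_px).all()
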