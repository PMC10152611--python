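import numpy as np
import pytest

import vitroscan as vs
from vitroscan.depth import (
    correct_and_segment,
    depth_traits,
    detect_medium_circle,
    edge_removed_mask,
    process_depth_scan,
    ransac_plane,
    zero_level,
)
from vitroscan.synth import DepthGrid, PlantBlob, SceneTruth


def grid_from_raw(raw, valid=None):
    raw = np.asarray(raw, dtype=float)
    return DepthGrid(raw=raw, valid=np.ones_like(raw, bool) if valid is None else valid)


class TestZeroLevel:
    def test_uniform_grid(self):
        assert zero_level(grid_from_raw(np.full((30, 30), 19430.0))) == 19430.0

    def test_interior_does_not_leak_into_corners(self):
        raw = np.full((40, 40), 19430.0)
        raw[12:28, 12:28] += 1000.0
        assert zero_level(grid_from_raw(raw)) == 19430.0

    def test_invalid_corner_excluded(self):
        raw = np.full((40, 40), 19430.0)
        valid = np.ones_like(raw, bool)
        valid[:10, :10] = False  # one corner entirely dropped out
        raw[:10, :10] = 99999.0
        assert zero_level(grid_from_raw(raw, valid)) == 19430.0

    def test_all_corners_invalid_errors(self):
        raw = np.full((30, 30), 19430.0)
        with pytest.raises(ValueError):
            zero_level(grid_from_raw(raw, np.zeros_like(raw, bool)))


class TestMediumCircle:
    def test_synthetic_disk_found_within_a_pixel(self, laser_cal):
        scene = SceneTruth(medium_height_mm=20.0, noise_sd_mm=0.0, seed=1)
        grid = vs.render_depth(scene, laser_cal)
        h = vs.depth.heights_from_grid(grid, laser_cal, zero_level(grid))
        (cy, cx), r = detect_medium_circle(h)
        assert r == pytest.approx(37.0, abs=1.0)
        assert cy == pytest.approx(49.5, abs=1.0) and cx == pytest.approx(49.5, abs=1.0)

    def test_noisy_disk_found_within_a_pixel(self, laser_cal):
        scene = SceneTruth(medium_height_mm=20.0, noise_sd_mm=0.1, seed=2)
        grid = vs.render_depth(scene, laser_cal)
        h = vs.depth.heights_from_grid(grid, laser_cal, zero_level(grid))
        _, r = detect_medium_circle(h)
        assert r == pytest.approx(37.0, abs=1.0)

    def test_flat_grid_errors(self):
        with pytest.raises(ValueError):
            detect_medium_circle(np.zeros((100, 100)))


class TestEdgeRemovedMask:
    def test_rim_strip_reduces_radius_by_3(self):
        mask = edge_removed_mask((49.5, 49.5), 37.0, (100, 100))
        rr, cc = np.mgrid[0:100, 0:100]
        expected = np.hypot(rr - 49.5, cc - 49.5) <= 34.0
        assert np.array_equal(mask, expected)

    def test_radius_too_small_errors(self):
        with pytest.raises(ValueError):
            edge_removed_mask((5.0, 5.0), 3.0, (10, 10))

    def test_tiny_disk_rasterizes(self):
        mask = edge_removed_mask((5.0, 5.0), 4.0, (11, 11))
        rr, cc = np.mgrid[0:11, 0:11]
        assert np.array_equal(mask, np.hypot(rr - 5, cc - 5) <= 1.0)


class TestRansacPlane:
    def test_outlier_contaminated_plane_recovered_exactly(self):
        rng = np.random.default_rng(0)
        rr, cc = np.mgrid[0:60, 0:60]
        z = 20.0 + 0.01 * cc  # x-tilted plane
        out = rng.random((60, 60)) < 0.05
        z = np.where(out, 40.0, z)
        model = ransac_plane(z, np.ones_like(z, bool), seed=1, iterations=2000)
        assert model.plane[0] == pytest.approx(0.01, abs=1e-6)
        assert model.plane[1] == pytest.approx(0.0, abs=1e-6)
        assert model.plane[2] == pytest.approx(20.0, abs=1e-6)
        assert not model.inlier_mask[out].any()

    def test_flat_heights_give_horizontal_plane(self):
        z = np.full((30, 30), 20.0)
        model = ransac_plane(z, np.ones_like(z, bool), seed=0, iterations=200)
        assert model.plane == pytest.approx((0.0, 0.0, 20.0), abs=1e-12)

    def test_noisy_plane_within_three_standard_errors(self):
        rng = np.random.default_rng(7)
        rr, cc = np.mgrid[0:80, 0:80]
        sd = 0.1
        z = 18.0 + 0.015 * cc - 0.01 * rr + rng.normal(0, sd, (80, 80))
        model = ransac_plane(z, np.ones_like(z, bool), seed=3)
        n = model.inlier_mask.sum()
        se_c = sd / np.sqrt(n)
        assert model.plane[2] == pytest.approx(18.0 - 0.01 * 0 + 0.0, abs=10 * se_c)
        assert model.plane[0] == pytest.approx(0.015, abs=3 * sd / np.sqrt(n) / np.std(cc))
        assert model.plane[1] == pytest.approx(-0.01, abs=3 * sd / np.sqrt(n) / np.std(rr))

    def test_seeded_runs_are_bit_identical(self):
        rng = np.random.default_rng(1)
        z = 20.0 + rng.normal(0, 0.1, (50, 50))
        m1 = ransac_plane(z, np.ones_like(z, bool), seed=5, iterations=500)
        m2 = ransac_plane(z, np.ones_like(z, bool), seed=5, iterations=500)
        assert m1.plane == m2.plane
        assert np.array_equal(m1.inlier_mask, m2.inlier_mask)

    def test_too_few_points_errors(self):
        z = np.full((5, 5), 1.0)
        mask = np.zeros((5, 5), bool)
        mask[0, 0] = mask[0, 1] = True
        with pytest.raises(ValueError):
            ransac_plane(z, mask)


class TestCorrectAndSegment:
    def test_pure_plane_yields_all_zero(self):
        rr, cc = np.mgrid[0:40, 0:40]
        z = 20.0 + 0.01 * cc
        mask = np.ones_like(z, bool)
        model = ransac_plane(z, mask, seed=0, iterations=500)
        corrected = correct_and_segment(z, model, mask)
        assert np.nanmax(np.abs(corrected)) == 0.0

    def test_cone_height_survives_correction(self, laser_cal):
        scene = SceneTruth(
            plants=[PlantBlob((50.0, 50.0), 10.0, 15.0, shape="cone")],
            noise_sd_mm=0.0, dropout_slope_threshold=10.0, seed=4,
        )
        grid = vs.render_depth(scene, laser_cal)
        traits, model, corrected = process_depth_scan(grid, laser_cal, seed=0)
        # rasterisation oracle: the apex lies between grid samples, so the
        # highest sampled cone point sits min-distance/radius below 15 mm
        rr, cc = np.mgrid[0:100, 0:100]
        d = np.hypot((cc + 0.5) - 50.0, (rr + 0.5) - 50.0)
        expected = 15.0 * (1.0 - d.min() / 10.0)
        assert np.nanmax(corrected) == pytest.approx(expected, abs=0.05)

    def test_plant_pixels_bounded_by_mask(self, laser_cal):
        grid = vs.render_depth(vs.default_scene(8), laser_cal)
        traits, model, corrected = process_depth_scan(grid, laser_cal, seed=0)
        mask = edge_removed_mask(model.circle_center_px, model.circle_radius_px, grid.raw.shape)
        assert traits.n_plant_px <= mask.sum()


class TestDepthTraits:
    @staticmethod
    def flat_model(height):
        from vitroscan.depth import MediumModel

        return MediumModel((50.0, 50.0), 37.0, (0.0, 0.0, float(height)))

    def frustum(self, r1, r2, h):
        mask = np.ones((10, 10), bool)
        plants = np.zeros((10, 10))
        tr = depth_traits(self.flat_model(h), plants, mask, top_radius_px=r1, r2_mm=r2)
        return tr.medium_volume_mm3

    def test_zero_height_zero_volume(self):
        assert self.frustum(20.0, 37.0, 0.0) == 0.0

    def test_cylinder_limit(self):
        assert self.frustum(37.0, 37.0, 3.0) == pytest.approx(np.pi * 37.0**2 * 3.0, rel=1e-12)

    def test_cone_limit(self):
        assert self.frustum(0.0, 37.0, 3.0) == pytest.approx(np.pi * 3.0 * 37.0**2 / 3.0, rel=1e-12)

    def test_upper_decile_mean_and_area(self):
        plants = np.zeros((10, 10))
        plants.flat[:20] = np.arange(1.0, 21.0)
        tr = depth_traits(self.flat_model(5.0), plants, np.ones((10, 10), bool))
        assert tr.max_plant_height_mm == pytest.approx(19.5)  # mean of {19, 20}
        assert tr.projected_area_depth_mm2 == pytest.approx(20.0)
        assert tr.avg_canopy_height_mm == pytest.approx(np.mean(np.arange(1.0, 21.0)))
        assert tr.max_plant_height_mm >= tr.avg_canopy_height_mm

    def test_no_plants_missing_heights(self):
        tr = depth_traits(self.flat_model(5.0), np.zeros((10, 10)), np.ones((10, 10), bool))
        assert tr.avg_canopy_height_mm is None
        assert tr.max_plant_height_mm is None
        assert tr.projected_area_depth_mm2 == 0.0


class TestFullPipeline:
    def test_medium_height_recovered_on_default_scene(self, laser_cal):
        scene = vs.default_scene(0)
        grid = vs.render_depth(scene, laser_cal)
        traits, model, corrected = process_depth_scan(grid, laser_cal, seed=0)
        n = model.inlier_mask.sum()
        tol = 3 * scene.noise_sd_mm * np.sqrt(1 / n + 1 / 400)
        assert traits.medium_height_mm == pytest.approx(scene.medium_height_mm, abs=tol)

    def test_depth_area_never_exceeds_truth_footprint(self, laser_cal):
        scene = vs.default_scene(12)
        grid = vs.render_depth(scene, laser_cal)
        traits, _, _ = process_depth_scan(grid, laser_cal, seed=0)
        rr, cc = np.mgrid[0:100, 0:100]
        foot = np.zeros((100, 100), bool)
        for p in scene.plants:
            foot |= np.hypot((cc + 0.5) - p.center_xy[0], (rr + 0.5) - p.center_xy[1]) <= p.radius_mm
        assert traits.n_plant_px <= foot.sum()
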