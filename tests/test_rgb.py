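import numpy as np
import pytest

import vitroscan as vs
from vitroscan.calibration import PixelMetric
from vitroscan.rgb import (
    PlantMask,
    downscale,
    extract_traits,
    find_plant_positions,
    is_night,
    otsu_threshold,
    segment,
    stretch_contrast,
    train_pixel_classifier,
)
from vitroscan.synth import VesselImage


def as_image(arr, **kw):
    return VesselImage(np.asarray(arr, dtype=np.uint8), **kw)


class TestStretchContrast:
    def test_constant_image_unchanged(self):
        img = as_image(np.full((10, 10, 3), 77))
        assert np.array_equal(stretch_contrast(img).pixels, img.pixels)

    def test_uniform_span_maps_to_full_range(self):
        # channel holding a dense uniform ramp over [50, 200]
        ramp = np.linspace(50, 200, 10000).reshape(100, 100)
        img = as_image(np.stack([ramp] * 3, axis=-1))
        out = stretch_contrast(img).pixels
        assert out.min() == 0 and out.max() == 255

    def test_full_range_uniform_nearly_unchanged(self):
        ramp = np.linspace(0, 255, 65536).reshape(256, 256)
        img = as_image(np.stack([ramp] * 3, axis=-1))
        out = stretch_contrast(img).pixels.astype(int)
        interior = (img.pixels.astype(int) > 10) & (img.pixels.astype(int) < 245)
        assert np.abs(out[interior] - img.pixels.astype(int)[interior]).max() <= 4


class TestDownscale:
    def test_published_resolution_reduction(self):
        img = as_image(np.zeros((3040, 4054, 3)))
        out = downscale(img, 4)
        assert (out.height_px, out.width_px) == (760, 1014)

    def test_constant_block_mean(self):
        img = as_image(np.full((4, 4, 3), 93))
        out = downscale(img, 4)
        assert out.pixels.shape == (1, 1, 3)
        assert (out.pixels == 93).all()

    def test_checkerboard_rounds_half_even(self):
        board = np.indices((4, 4)).sum(axis=0) % 2 * 255
        img = as_image(np.stack([board] * 3, axis=-1))
        out = downscale(img, 2)
        assert (out.pixels == 128).all()  # 127.5 rounds half-even to 128


class TestClassifier:
    def test_separable_two_color_scene_is_perfect(self):
        rng = np.random.default_rng(0)
        img = np.zeros((40, 40, 3), dtype=np.uint8)
        img[:, :20] = (40, 160, 60)  # plant-like green
        img[:, 20:] = (210, 205, 190)  # medium-like white
        labels = np.full((40, 40), -1, dtype=np.int8)
        rr, cc = rng.integers(0, 40, 100), rng.integers(0, 18, 100)
        labels[rr, cc] = 1
        rr, cc = rng.integers(0, 40, 100), rng.integers(22, 40, 100)
        labels[rr, cc] = 0
        clf = train_pixel_classifier([(as_image(img), labels)], seed=0)
        pred = clf.predict_mask(img)
        truth = np.zeros((40, 40), dtype=bool)
        truth[:, :20] = True
        interior = np.zeros_like(truth)
        interior[:, :18] = True
        interior[:, 22:] = True  # away from the colour boundary blur
        assert (pred == truth)[interior].all()

    def test_single_class_labels_error(self):
        img = as_image(np.zeros((10, 10, 3)))
        labels = np.zeros((10, 10), dtype=np.int8)  # background only
        with pytest.raises(ValueError):
            train_pixel_classifier([(img, labels)])

    def test_feature_bank_has_14_features(self):
        from vitroscan.rgb import FEATURE_NAMES, compute_features

        assert len(FEATURE_NAMES) == 14
        feats = compute_features(np.zeros((8, 8, 3), dtype=np.uint8))
        assert feats.shape == (8, 8, 14)

    def test_save_load_roundtrip(self, tmp_path, trained_classifier, pm_synthetic):
        path = tmp_path / "clf.joblib"
        trained_classifier.save(path)
        clf2 = vs.PixelClassifier.load(path)
        img, _ = vs.render_rgb(vs.random_scene(55), pm_synthetic)
        assert np.array_equal(
            trained_classifier.predict_mask(img.pixels), clf2.predict_mask(img.pixels)
        )


class TestSegment:
    def test_empty_scene_empty_mask(self, trained_classifier, pm_synthetic):
        from vitroscan.synth import SceneTruth

        img, _ = vs.render_rgb(SceneTruth(seed=3), pm_synthetic)
        mask = segment(img, trained_classifier)
        assert mask.mask.sum() == 0
        assert mask.n_components == 0

    def test_two_disjoint_blobs_two_components(self, trained_classifier, pm_synthetic):
        from vitroscan.synth import PlantBlob, SceneTruth

        scene = SceneTruth(
            plants=[
                PlantBlob((35.0, 50.0), 8.0, 10.0),
                PlantBlob((65.0, 50.0), 8.0, 10.0),
            ],
            seed=11,
        )
        img, _ = vs.render_rgb(scene, pm_synthetic)
        mask = segment(img, trained_classifier)
        big = [r for r in np.bincount(mask.labels.ravel())[1:] if r > 50]
        assert len(big) == 2

    def test_accuracy_against_renderer_truth(self, trained_classifier, pm_synthetic):
        img, truth = vs.render_rgb(vs.random_scene(200), pm_synthetic)
        mask = segment(img, trained_classifier)
        cs = vs.confusion_stats(mask.mask, truth)
        assert cs.accuracy >= 0.97

    def test_rescaling_preserves_mask_area_boundedly(self, trained_classifier, pm_synthetic):
        # upscaled mask area equals (factor^2) x downscaled-mask area, so the
        # area error vs a native-resolution mask is confined to boundary blocks
        img, truth = vs.render_rgb(vs.random_scene(201), pm_synthetic)
        mask = segment(img, trained_classifier, factor=4)
        small = mask.mask[::4, ::4]
        assert mask.mask.sum() == 16 * small.sum()


class TestTraits:
    def test_full_frame_coverage(self):
        mask = PlantMask.from_mask(np.ones((20, 20), dtype=bool))
        tr = extract_traits(mask)
        assert tr.degree_of_coverage == 1.0

    def test_disk_is_compact_and_solid(self):
        rr, cc = np.mgrid[0:120, 0:120]
        disk = np.hypot(rr - 60, cc - 60) <= 50
        tr = extract_traits(PlantMask.from_mask(disk))
        assert tr.solidity == pytest.approx(1.0, abs=0.05)
        # the 8-connected chain length overestimates a circle's perimeter by
        # ~5% (classic digital-geometry result), depressing stockiness ~10%
        assert tr.stockiness == pytest.approx(0.91, abs=0.05)

    def test_square_geometry_exact(self):
        m = np.zeros((20, 20), dtype=bool)
        m[5:15, 5:15] = True
        tr = extract_traits(PlantMask.from_mask(m))
        assert tr.projected_area_px == 100
        assert tr.convex_hull_area_px == 100
        assert tr.solidity == 1.0
        assert tr.perimeter_px == pytest.approx(36.0)  # 9-px sides, chain length

    def test_empty_mask_zeroed(self):
        tr = extract_traits(PlantMask.from_mask(np.zeros((10, 10), bool)))
        assert tr.projected_area_px == 0
        assert tr.n_objects == 0
        assert tr.solidity is None

    def test_cumulative_area_is_sum_of_objects(self, pm_synthetic):
        m = np.zeros((30, 30), dtype=bool)
        m[2:8, 2:8] = True
        m[15:25, 15:28] = True
        tr = extract_traits(PlantMask.from_mask(m), pm_synthetic)
        assert tr.projected_area_px == sum(o["area_px"] for o in tr.per_object)
        assert tr.degree_of_coverage * 900 == pytest.approx(tr.projected_area_px)
        assert tr.projected_area_mm2 == pytest.approx(tr.projected_area_px / 4.0)


class TestOtsuAndPositions:
    def brute_force_otsu(self, values):
        # exact enumeration in integer arithmetic (no float ties); the
        # between-class variance is proportional to (M*W0 - N*M0)^2/(W0*W1)
        from fractions import Fraction

        hist = np.bincount(values, minlength=256)
        N = int(hist.sum())
        M = int((np.arange(256) * hist).sum())
        best_t, best_v = 0, Fraction(-1)
        w0 = m0 = 0
        for t in range(256):
            w0 += int(hist[t])
            m0 += t * int(hist[t])
            w1 = N - w0
            if w0 == 0 or w1 == 0:
                continue
            v = Fraction((M * w0 - N * m0) ** 2, w0 * w1)
            if v > best_v:
                best_v, best_t = v, t
        return best_t

    def test_bimodal_histogram(self):
        vals = np.array([30] * 500 + [90] * 500)
        assert otsu_threshold(vals) == self.brute_force_otsu(vals)
        assert 30 <= otsu_threshold(vals) < 90

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_on_random_histograms(self, seed):
        rng = np.random.default_rng(seed)
        vals = np.concatenate(
            [
                rng.normal(rng.uniform(40, 100), rng.uniform(5, 20), 400),
                rng.normal(rng.uniform(120, 220), rng.uniform(5, 20), 600),
            ]
        )
        vals = np.clip(np.rint(vals), 0, 255).astype(np.int64)
        assert otsu_threshold(vals) == self.brute_force_otsu(vals)

    def test_centered_blob_zero_offset(self):
        img = np.zeros((101, 101, 3), dtype=np.uint8)
        img[:] = (200, 200, 200)
        rr, cc = np.mgrid[0:101, 0:101]
        blob = np.hypot(rr - 50, cc - 50) <= 10
        img[blob] = (40, 160, 60)
        pos = find_plant_positions(as_image(img), (120.0, 80.0), PixelMetric(2.0))
        assert len(pos) == 1
        assert pos[0][0] == pytest.approx(120.0, abs=0.3)
        assert pos[0][1] == pytest.approx(80.0, abs=0.3)

    def test_four_largest_of_six_blobs(self):
        img = np.zeros((200, 200, 3), dtype=np.uint8)
        img[:] = (200, 200, 200)
        rr, cc = np.mgrid[0:200, 0:200]
        radii = [4, 6, 8, 10, 12, 14]
        centers = [(30, 30), (30, 100), (30, 170), (140, 30), (140, 100), (140, 170)]
        for r, (y, x) in zip(radii, centers):
            img[np.hypot(rr - y, cc - x) <= r] = (40, 160, 60)
        pos = find_plant_positions(as_image(img), (0.0, 0.0), PixelMetric(1.0))
        assert len(pos) == 4
        got = {(round(x), round(y)) for x, y in pos}
        mid = 199 / 2
        expected = {
            (round(x - mid), round(y - mid))
            for (y, x), r in zip(centers, radii)
            if r >= 8
        }
        assert got == expected


class TestNightDetection:
    def test_black_frame_is_night(self):
        assert is_night(as_image(np.zeros((4, 4, 3))))

    def test_bright_frame_is_day(self):
        assert not is_night(as_image(np.full((4, 4, 3), 255)))

    def test_exact_threshold_is_day(self):
        img = as_image(np.full((4, 4, 3), 30))
        assert not is_night(img, threshold=30.0)  # strict inequality
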