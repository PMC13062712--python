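import math

import numpy as np
import pytest

from seedpheno import (
    DESCRIPTOR_NAMES,
    SeedDescriptors,
    compute_descriptors,
    fit_ellipse,
    glcm_features,
    overlap_ratio,
)
from seedpheno.features import (
    DESCRIPTOR_GROUPS,
    FittedEllipse,
    GLCM_LEVELS,
    glcm_matrices,
    rasterize_ellipse,
)
from seedpheno.imaging import CalibratedImage, preprocess
from seedpheno.segmentation import mask_from_full


def ellipse_mask(a, b, theta=0.0, size=120):
    c = size // 2
    yy, xx = np.mgrid[0:size, 0:size]
    dx, dy = xx - c, yy - c
    u = (dx * math.cos(theta) + dy * math.sin(theta)) / a
    v = (-dx * math.sin(theta) + dy * math.cos(theta)) / b
    return mask_from_full(u**2 + v**2 <= 1.0, "threshold")


class TestDescriptorContract:
    def test_38_names_and_group_sizes(self):
        assert len(DESCRIPTOR_NAMES) == 38
        sizes = {g: hi - lo for g, (lo, hi) in DESCRIPTOR_GROUPS.items()}
        assert sizes == {"color": 21, "shape": 9, "texture": 5, "position": 3}

    def test_record_validates_length_and_finiteness(self):
        with pytest.raises(ValueError):
            SeedDescriptors("img", 0, np.zeros(37))
        vals = np.zeros(38)
        vals[3] = np.nan
        with pytest.raises(ValueError):
            SeedDescriptors("img", 0, vals)


class TestFitEllipse:
    def test_axis_aligned_ellipse_recovered(self):
        m = ellipse_mask(30, 15)
        ell = fit_ellipse(m)
        assert ell.major == pytest.approx(30, rel=0.02)
        assert ell.minor == pytest.approx(15, rel=0.02)
        assert min(ell.theta, math.pi - ell.theta) < 0.05

    def test_disc_is_isotropic(self):
        m = ellipse_mask(10, 10)
        ell = fit_ellipse(m)
        assert ell.major == pytest.approx(ell.minor, rel=0.02)

    def test_rotation_shifts_theta_only(self):
        m0 = ellipse_mask(30, 15, theta=0.3)
        m90 = ellipse_mask(30, 15, theta=0.3 + math.pi / 2)
        e0, e90 = fit_ellipse(m0), fit_ellipse(m90)
        assert e90.major == pytest.approx(e0.major, rel=0.02)
        assert e90.minor == pytest.approx(e0.minor, rel=0.02)
        delta = (e90.theta - e0.theta) % math.pi
        assert min(delta, math.pi - delta) == pytest.approx(math.pi / 2, abs=0.05)

    def test_degenerate_line_clamped(self):
        mask = np.zeros((40, 40), dtype=bool)
        mask[20, 5:35] = True
        m = mask_from_full(mask, "threshold")
        ell = fit_ellipse(m)
        assert ell.degenerate and ell.minor == 0.5


class TestOverlapRatio:
    def test_self_ellipse_is_one(self):
        ell = FittedEllipse(cx=60, cy=60, major=25, minor=12, theta=0.4)
        raster = rasterize_ellipse(ell, (0, 0, 120, 120))
        m = mask_from_full(raster, "threshold")
        assert overlap_ratio(m, ell) == 1.0

    @pytest.mark.parametrize("a,b,theta", [(20, 12, 0.0), (25, 15, 0.7), (30, 10, 1.2)])
    def test_true_ellipses_above_097(self, a, b, theta):
        m = ellipse_mask(a, b, theta)
        assert m.area_px >= 500
        assert overlap_ratio(m) >= 0.97

    def test_plus_shape_below_085(self):
        mask = np.zeros((60, 60), dtype=bool)
        mask[25:35, 10:50] = True  # horizontal 40x10 bar
        mask[10:50, 25:35] = True  # vertical 40x10 bar
        m = mask_from_full(mask, "threshold")
        ov = overlap_ratio(m)
        # brute-force check against an independent pixel count
        ell = fit_ellipse(m)
        raster = rasterize_ellipse(ell, (0, 0, 60, 60))
        full = m.full_mask((60, 60))
        oracle = (raster & full).sum() / (raster | full).sum()
        assert ov == pytest.approx(oracle, abs=1e-9)
        assert ov < 0.85


class TestGLCM:
    def _mask_for(self, arr):
        return mask_from_full(np.ones_like(arr, dtype=bool), "threshold")

    def test_constant_seed_convention(self):
        crop = np.full((10, 10), 100, dtype=np.uint8)
        feats = glcm_features(crop, self._mask_for(crop))
        np.testing.assert_allclose(feats, [0.0, 0.0, 1.0, 1.0, 0.0])

    def test_checkerboard_matches_pair_counting(self):
        # alternate quantization levels 0 and 31 (grey 0 and 255)
        crop = np.indices((8, 8)).sum(axis=0) % 2 * 255
        crop = crop.astype(np.uint8)
        mats = glcm_matrices(crop, np.ones((8, 8), dtype=bool))
        # 0 deg and 90 deg: all pairs differ by 31 levels -> contrast 31^2
        for a in (0, 2):
            p = mats[a]
            i, j = np.mgrid[0:GLCM_LEVELS, 0:GLCM_LEVELS]
            assert (p * (i - j) ** 2).sum() == pytest.approx(31**2)
        # diagonals: all pairs equal -> zero contrast
        for a in (1, 3):
            p = mats[a]
            i, j = np.mgrid[0:GLCM_LEVELS, 0:GLCM_LEVELS]
            assert (p * (i - j) ** 2).sum() == 0.0

    def test_mask_restricts_pairs_to_inside(self):
        # brute-force enumeration of in-mask horizontal pairs
        rng = np.random.default_rng(3)
        crop = rng.integers(0, 256, size=(12, 12)).astype(np.uint8)
        mask = np.zeros((12, 12), dtype=bool)
        mask[3:9, 2:10] = True
        q = (crop.astype(int) * GLCM_LEVELS) // 256
        expect = np.zeros((GLCM_LEVELS, GLCM_LEVELS))
        for r in range(12):
            for c in range(11):
                if mask[r, c] and mask[r, c + 1]:
                    expect[q[r, c], q[r, c + 1]] += 1
        expect = expect + expect.T
        expect /= expect.sum()
        p0 = glcm_matrices(crop, mask)[0]
        np.testing.assert_allclose(p0, expect)

    def test_noise_vs_constant_ordering(self):
        rng = np.random.default_rng(0)
        noisy = rng.integers(0, 256, size=(16, 16)).astype(np.uint8)
        flat = np.full((16, 16), 80, dtype=np.uint8)
        m = np.ones((16, 16), dtype=bool)
        fn = glcm_features(noisy, mask_from_full(m, "threshold"))
        fc = glcm_features(flat, mask_from_full(m, "threshold"))
        assert fn[0] > fc[0]  # contrast strictly higher
        assert fn[3] < fc[3]  # energy strictly lower

    def test_small_mask_rejected(self):
        crop = np.zeros((3, 3), dtype=np.uint8)
        with pytest.raises(ValueError):
            glcm_features(crop, mask_from_full(np.ones((3, 3), bool)[:2, :2], "t"))


class TestComputeDescriptors:
    def _uniform_disc_image(self):
        px = np.full((128, 128, 3), 255, dtype=np.uint8)
        yy, xx = np.mgrid[0:128, 0:128]
        mask = (yy - 64) ** 2 + (xx - 64) ** 2 <= 20**2
        px[mask] = 128
        img = CalibratedImage(pixels=px, source_id="unidisc")
        pre = preprocess(img)
        from seedpheno.segmentation import segment_image

        return pre, segment_image(pre)

    def test_uniform_disc_statistics(self):
        pre, masks = self._uniform_disc_image()
        recs = compute_descriptors(pre, masks)
        assert len(recs) == 1
        r = recs[0]
        assert r["mean_r"] == pytest.approx(r["mean_g"], abs=1e-9)
        assert r["mean_g"] == pytest.approx(r["mean_b"], abs=1e-9)
        assert r["std_grey"] < 2.0
        assert r["eccentricity"] < 0.25
        assert r["nn_distance"] == pytest.approx(math.hypot(128, 128))

    def test_grey_mean_matches_brute_force(self, small_scene_processed):
        pre, masks, recs = small_scene_processed
        by_index = {m.seed_index: m for m in masks}
        for r in recs[:10]:
            m = by_index[r.seed_index]
            full = m.full_mask(pre.grey.shape)
            oracle = pre.grey[full].astype(np.float64).mean()
            assert r["mean_grey"] == pytest.approx(oracle, abs=1e-6)

    def test_group_ranges(self, small_scene_processed):
        _, _, recs = small_scene_processed
        for r in recs:
            assert np.all(np.isfinite(r.values))
            for name in ("overlap_ratio", "solidity", "extent",
                         "glcm_homogeneity", "glcm_energy"):
                assert 0.0 <= r[name] <= 1.0, name
            assert 0.0 <= r["eccentricity"] < 1.0
            assert 0.0 < r["circularity"] <= 1.1
            assert r["convexity"] <= 1.0 + 0.05

    def test_parallel_equals_serial(self, small_scene_processed):
        pre, masks, _ = small_scene_processed
        serial = compute_descriptors(pre, masks, n_jobs=1)
        parallel = compute_descriptors(pre, masks, n_jobs=2)
        for a, b in zip(serial, parallel):
            np.testing.assert_array_equal(a.values, b.values)

    def test_rotation_robustness(self):
        from seedpheno import SceneSpec, generate_scene
        from seedpheno.pipeline import process_image

        spec = SceneSpec(n_seeds=12, cluster_fraction=0.0,
                         image_size=(384, 384), rng_seed=21)
        truth = generate_scene(spec)
        _, _, recs = process_image(truth.image)
        rot = CalibratedImage(
            pixels=np.ascontiguousarray(np.rot90(truth.image.pixels)),
            source_id="rot",
        )
        _, _, recs_r = process_image(rot)
        assert len(recs) == len(recs_r) == 12
        key = lambda r: (round(r["area_px"], -1), round(r["mean_grey"], 0))
        for a, b in zip(sorted(recs, key=key), sorted(recs_r, key=key)):
            assert b["area_px"] == a["area_px"]
            assert b["perimeter_px"] == pytest.approx(a["perimeter_px"], rel=0.02)
            assert abs(b["eccentricity"] - a["eccentricity"]) <= 0.02
            assert abs(b["overlap_ratio"] - a["overlap_ratio"]) <= 0.03
            np.testing.assert_allclose(
                b.values[30:35], a.values[30:35], atol=1e-9
            )
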