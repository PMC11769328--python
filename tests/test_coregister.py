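"""Homography estimation, warping, stacking and the method comparison."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hyperseed.coregister import (
    HomographyTransform,
    TiePointSet,
    apply_homography,
    compare_methods,
    compute_scale,
    estimate_homography,
    resample_naive,
    stack_cubes,
    warp_cube,
)
from hyperseed.envi import SpectralCube
from hyperseed.synthetic import SceneSpec, generate_scene


class TestComputeScale:
    def test_double(self):
        s = compute_scale((200, 200), (100, 100))
        assert (s.scale_h, s.scale_w) == (2.0, 2.0)

    def test_identity(self):
        s = compute_scale((128, 96), (128, 96))
        assert (s.scale_h, s.scale_w) == (1.0, 1.0)

    def test_anisotropic(self):
        s = compute_scale((3000, 1200), (640, 480))
        assert (s.scale_h, s.scale_w) == (4.6875, 2.5)

    def test_zero_dims_rejected(self):
        with pytest.raises(ValueError):
            compute_scale((0, 10), (5, 5))


class TestResampleNaive:
    def test_identity_target(self, random_cube):
        out = resample_naive(random_cube, random_cube.shape[:2])
        np.testing.assert_array_equal(out.data, random_cube.data)

    def test_constant_cube_stays_constant(self):
        cube = SpectralCube(np.full((4, 4, 2), 3.0), [400, 500])
        out = resample_naive(cube, (2, 2))
        assert np.allclose(out.data, 3.0)

    def test_integer_downscale_is_block_mean(self):
        data = np.zeros((4, 4, 1))
        data[:2, :2, 0] = 1.0
        data[2:, 2:, 0] = 3.0
        cube = SpectralCube(data, [500.0])
        out = resample_naive(cube, (2, 2))
        expected = np.array([[1.0, 0.0], [0.0, 3.0]])
        np.testing.assert_allclose(out.data[:, :, 0], expected)


class TestApplyHomography:
    def test_identity(self):
        h = HomographyTransform.identity()
        assert apply_homography((3.5, -2.0), h) == (3.5, -2.0)

    def test_affine_case(self):
        h = HomographyTransform([[2, 0, 3], [0, 2, -1], [0, 0, 1]])
        assert apply_homography((1.0, 1.0), h) == (5.0, 1.0)

    def test_projective_division(self):
        h = HomographyTransform([[1, 0, 0], [0, 1, 0], [1, 0, 1]])
        x, y = apply_homography((1.0, 0.0), h)
        assert (x, y) == (0.5, 0.0)

    def test_zero_denominator_rejected(self):
        h = HomographyTransform([[1, 0, 0], [0, 1, 0], [-1, 0, 1]])
        with pytest.raises(ZeroDivisionError):
            apply_homography((1.0, 0.0), h)


class TestEstimateHomography:
    def test_exact_translation_from_four_points(self):
        src = np.array([[0, 0], [10, 0], [0, 10], [10, 10]], float)
        ref = src + np.array([4.0, -2.5])
        h, report = estimate_homography(TiePointSet(src, ref))
        expected = np.array([[1, 0, 4.0], [0, 1, -2.5], [0, 0, 1]])
        np.testing.assert_allclose(h.h, expected, atol=1e-9)
        assert report.rmse < 1e-9

    def test_ransac_excludes_gross_outliers(self):
        rng = np.random.default_rng(7)
        truth = HomographyTransform.scale_translate(0.5, 0.6, 8.0, -3.0)
        src = rng.uniform(0, 400, (12, 2))
        ref = truth(src)
        out_src = rng.uniform(0, 400, (3, 2))
        out_ref = truth(out_src) + rng.uniform(55, 90, (3, 2))
        tp = TiePointSet(np.vstack([src, out_src]), np.vstack([ref, out_ref]))
        h, report = estimate_homography(tp, ransac_threshold=7.0, rng_seed=1)
        assert report.inlier_count == 12
        probe = rng.uniform(0, 400, (50, 2))
        np.testing.assert_allclose(h(probe), truth(probe), atol=0.5)

    def test_collinear_points_rejected(self):
        src = np.array([[0, 0], [1, 1], [2, 2], [3, 3]], float)
        with pytest.raises(ValueError, match="collinear"):
            estimate_homography(TiePointSet(src, src + 1))

    def test_fewer_than_four_pairs_rejected(self):
        with pytest.raises(ValueError):
            TiePointSet(np.zeros((3, 2)), np.zeros((3, 2)))

    @settings(derandomize=True, max_examples=20)
    @given(st.floats(0.3, 3.0), st.floats(0.3, 3.0),
           st.floats(-30, 30), st.floats(-30, 30))
    def test_recovers_random_scale_translation(self, sx, sy, tx, ty):
        truth = HomographyTransform.scale_translate(sx, sy, tx, ty)
        rng = np.random.default_rng(3)
        src = rng.uniform(0, 300, (10, 2))
        h, _ = estimate_homography(TiePointSet(src, truth(src)), rng_seed=0)
        assert np.linalg.norm(h.h - truth.h) < 1e-6


class TestWarpCube:
    def test_identity_is_noop(self, random_cube):
        out = warp_cube(random_cube, HomographyTransform.identity(),
                        random_cube.shape[:2])
        np.testing.assert_allclose(out.data, random_cube.data, atol=1e-12)

    def test_integer_translation_is_pixel_exact(self, random_cube):
        h = HomographyTransform.scale_translate(1, 1, 2.0, 1.0)
        out = warp_cube(random_cube, h, random_cube.shape[:2])
        np.testing.assert_allclose(out.data[1:, 2:, :],
                                   random_cube.data[:-1, :-2, :], atol=1e-12)
        assert np.all(out.data[:1, :, :] == 0)

    def test_simulated_pair_markers_align_after_warp(self):
        spec = SceneSpec(grid_rows=2, grid_cols=2, protein_pct=[8, 12, 16, 19],
                         noise_sd=0.0, rng_seed=4)
        scene = generate_scene(spec)
        warped = warp_cube(scene.vnir, scene.truth_transform,
                           scene.swir.shape[:2])
        # marker disks are the brightest element; compare centroids per frame
        from skimage.measure import label, regionprops

        def centroids(img):
            mask = img > 0.7
            return np.array(sorted((r.centroid[1], r.centroid[0])
                                   for r in regionprops(label(mask))))

        a = centroids(warped.data[:, :, 0])
        b = centroids(scene.swir.data[:, :, 0])
        assert len(a) == len(b)
        assert np.all(np.linalg.norm(a - b, axis=1) < 1.0)


class TestStackCubes:
    def test_band_counts_add(self):
        wl_a = np.linspace(400, 1000, 300)
        wl_b = np.linspace(960, 2500, 362)
        a = SpectralCube(np.zeros((4, 5, 300)), wl_a)
        b = SpectralCube(np.ones((4, 5, 362)), wl_b)
        out = stack_cubes(a, b)
        assert out.n_bands == 662
        np.testing.assert_array_equal(out.wavelengths,
                                      np.concatenate([wl_a, wl_b]))

    def test_minimal_stack(self):
        a = SpectralCube(np.zeros((2, 2, 1)), [500.0])
        b = SpectralCube(np.ones((2, 2, 1)), [1500.0])
        assert stack_cubes(a, b).n_bands == 2

    def test_spatial_mismatch_rejected(self):
        a = SpectralCube(np.zeros((2, 2, 1)), [500.0])
        b = SpectralCube(np.ones((3, 2, 1)), [1500.0])
        with pytest.raises(ValueError):
            stack_cubes(a, b)


class TestCompareMethods:
    def test_pure_resolution_ratio_scene_both_near_zero(self):
        """With no shift and scale equal to the dims ratio, both methods win."""
        from types import SimpleNamespace

        rng = np.random.default_rng(5)
        vnir = SpectralCube(np.zeros((200, 100, 1)), [500.0])
        swir = SpectralCube(np.zeros((100, 50, 1)), [1500.0])
        markers = rng.uniform(5, 95, (10, 2)) * np.array([1.0, 2.0])
        truth = HomographyTransform.scale_translate(0.5, 0.5, 0.0, 0.0)
        scene = SimpleNamespace(vnir=vnir, swir=swir, vnir_markers=markers,
                                swir_markers=truth(markers))
        reports = compare_methods(scene, rng_seed=0)
        assert reports["homography"].rmse < 1e-9
        assert reports["resampling"].rmse < 1e-9

    def test_translation_makes_homography_win(self):
        for seed in range(3):
            scene = generate_scene(SceneSpec(grid_rows=2, grid_cols=2,
                                             protein_pct=[8, 12, 16, 19],
                                             noise_sd=0.0, rng_seed=seed))
            reports = compare_methods(scene, rng_seed=seed)
            assert reports["homography"].rmse < reports["resampling"].rmse

    def test_deterministic_given_seed(self, small_scene):
        a = compare_methods(small_scene, rng_seed=9)
        b = compare_methods(small_scene, rng_seed=9)
        assert a == b
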