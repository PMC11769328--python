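"""Rule mask, morphology, hole repair, components, grid labels and crops."""

import numpy as np
import pandas as pd
import pytest

from hyperseed.envi import SpectralCube
from hyperseed.segmentation import (
    RuleBandSet,
    crop_seed,
    extract_components,
    grid_label,
    morphological_open,
    repair_holes,
    resolve_rule_bands,
    rgb_composite,
    rule_mask,
    segment_scene,
)
from hyperseed.synthetic import SceneSpec, generate_scene

RULE_BANDS = RuleBandSet(0, 1, 2, 3, 4)


def _pixel_cube(b1, b2, g, r, n):
    data = np.array([[[b1, b2, g, r, n]]], dtype=float)
    return SpectralCube(data, [410, 456, 553, 654, 852])


class TestRuleMask:
    def test_seed_like_pixel_passes_all_conditions(self):
        # by hand: 0.05<0.07; 0.035<=0.06<=0.625; 0.06<=0.30<=0.75;
        # 0.07<0.10; 0.084<0.10
        cube = _pixel_cube(0.05, 0.07, 0.10, 0.06, 0.30)
        assert rule_mask(cube, RULE_BANDS)[0, 0] == 1

    def test_flat_panel_pixel_fails(self):
        cube = _pixel_cube(0.5, 0.5, 0.5, 0.5, 0.5)
        assert rule_mask(cube, RULE_BANDS)[0, 0] == 0

    def test_all_zero_pixel_fails_strict_inequalities(self):
        cube = _pixel_cube(0.0, 0.0, 0.0, 0.0, 0.0)
        assert rule_mask(cube, RULE_BANDS)[0, 0] == 0

    def test_band_indices_must_be_distinct(self):
        with pytest.raises(ValueError):
            RuleBandSet(0, 0, 2, 3, 4)

    def test_resolve_on_vnir_grid(self):
        wl = np.linspace(400, 1000, 300)
        cube = SpectralCube(np.zeros((1, 1, 300)), wl)
        bands = resolve_rule_bands(cube)
        for idx, target in zip(
                (bands.b1_idx, bands.b2_idx, bands.g_idx, bands.r_idx, bands.n_idx),
                (410, 456, 553, 654, 852)):
            assert abs(wl[idx] - target) <= np.diff(wl)[0] / 2


class TestMorphologicalOpen:
    def test_isolated_pixel_removed(self):
        mask = np.zeros((7, 7), dtype=np.uint8)
        mask[3, 3] = 1
        assert morphological_open(mask).sum() == 0

    def test_solid_block_preserved(self):
        mask = np.zeros((9, 9), dtype=np.uint8)
        mask[2:7, 2:7] = 1
        np.testing.assert_array_equal(morphological_open(mask), mask)

    def test_diagonal_appendage_removed_core_kept(self):
        mask = np.zeros((8, 8), dtype=np.uint8)
        mask[2:5, 2:5] = 1
        mask[5, 5] = 1  # diagonal single pixel off the 3x3 core
        out = morphological_open(mask)
        assert out[5, 5] == 0
        assert out[2:5, 2:5].all()

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        mask = (rng.uniform(size=(40, 40)) < 0.4).astype(np.uint8)
        once = morphological_open(mask)
        np.testing.assert_array_equal(morphological_open(once), once)


class TestRepairHoles:
    def test_ring_interior_filled(self):
        mask = np.zeros((9, 9), dtype=np.uint8)
        mask[2:7, 2:7] = 1
        mask[4, 4] = 0  # hole
        out = repair_holes(mask)
        assert out[4, 4] == 1

    def test_all_zero_stays_background(self):
        out = repair_holes(np.zeros((5, 5), dtype=np.uint8))
        assert out.sum() == 0

    def test_edge_touching_background_still_floods(self):
        mask = np.ones((5, 5), dtype=np.uint8)
        mask[0, 0] = 0  # seed region touches every frame edge
        out = repair_holes(mask)
        # the single corner background pixel is reachable via the guard border
        assert out[0, 0] == 0

    def test_never_removes_seed_pixels(self):
        rng = np.random.default_rng(2)
        mask = (rng.uniform(size=(30, 30)) < 0.3).astype(np.uint8)
        out = repair_holes(mask)
        assert np.all(out[mask == 1] == 1)


class TestExtractComponents:
    @staticmethod
    def _disk(radius, at, shape=(80, 80)):
        mask = np.zeros(shape, dtype=np.uint8)
        yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
        mask[(yy - at[0]) ** 2 + (xx - at[1]) ** 2 <= radius ** 2] = 1
        return mask

    def test_small_blob_dropped(self):
        table = extract_components(self._disk(5, (20, 20)))  # area ~ 79
        assert table.empty

    def test_seed_sized_blob_retained(self):
        table = extract_components(self._disk(14, (40, 40)))  # area ~ 615
        assert len(table) == 1
        assert 250 < table.iloc[0]["area"] < 1500

    def test_fused_blob_dropped(self):
        table = extract_components(self._disk(26, (40, 40)))  # area ~ 2100
        assert table.empty


class TestGridLabel:
    def test_exact_lattice_row_major(self):
        rows, cols = 6, 4
        records = []
        for r in range(rows):
            for c in range(cols):
                records.append({"component_id": r * cols + c + 1, "area": 600,
                                "min_row": r * 50, "max_row": r * 50 + 20,
                                "min_col": c * 50, "max_col": c * 50 + 10,
                                "centroid_x": c * 50.0 + 5,
                                "centroid_y": r * 50.0 + 10})
        table = grid_label(pd.DataFrame(records), rows, cols)
        expected = [f"{chr(ord('A') + c)}{r + 1}"
                    for r in range(rows) for c in range(cols)]
        assert table["grid_label"].tolist() == expected

    def test_single_component_is_a1(self):
        table = grid_label(pd.DataFrame([{
            "component_id": 1, "area": 600, "min_row": 0, "max_row": 20,
            "min_col": 0, "max_col": 10, "centroid_x": 5.0, "centroid_y": 10.0,
        }]))
        assert table["grid_label"].tolist() == ["A1"]

    def test_same_row_ordered_by_x(self):
        records = [
            {"component_id": 1, "area": 600, "min_row": 0, "max_row": 20,
             "min_col": 50, "max_col": 60, "centroid_x": 55.0, "centroid_y": 10.0},
            {"component_id": 2, "area": 600, "min_row": 0, "max_row": 20,
             "min_col": 0, "max_col": 10, "centroid_x": 5.0, "centroid_y": 11.0},
        ]
        table = grid_label(pd.DataFrame(records))
        assert table["grid_label"].tolist() == ["B1", "A1"]

    def test_overflow_rejected(self):
        records = [{"component_id": i, "area": 600, "min_row": 0, "max_row": 5,
                    "min_col": 0, "max_col": 5, "centroid_x": float(i),
                    "centroid_y": 1.0} for i in range(5)]
        with pytest.raises(ValueError):
            grid_label(pd.DataFrame(records), rows=2, cols=2)


class TestCropSeed:
    @staticmethod
    def _cube_with_blob(center, shape=(60, 60, 4)):
        rng = np.random.default_rng(3)
        data = rng.uniform(0.2, 0.8, shape)
        labeled = np.zeros(shape[:2], dtype=int)
        yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
        labeled[(yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= 36] = 1
        cube = SpectralCube(data, np.linspace(400, 700, shape[2]))
        comp = pd.Series({"component_id": 1,
                          "centroid_x": float(center[1]),
                          "centroid_y": float(center[0]),
                          "grid_label": "A1"})
        return cube, comp, labeled

    def test_patch_is_32_square_and_centered(self):
        cube, comp, labeled = self._cube_with_blob((30, 30))
        crop = crop_seed(cube, comp, labeled)
        assert crop.patch.shape == (32, 32, 4)
        mask = np.any(crop.patch != 0, axis=2)
        ys, xs = np.nonzero(mask)
        assert abs(ys.mean() - 16) <= 1 and abs(xs.mean() - 16) <= 1

    def test_corner_component_zero_padded(self):
        cube, comp, labeled = self._cube_with_blob((2, 2))
        crop = crop_seed(cube, comp, labeled)
        assert crop.patch.shape == (32, 32, 4)
        # rows/cols mapped from outside the frame stay zero
        assert np.all(crop.patch[0, :, :] == 0)
        assert np.all(crop.patch[:, 0, :] == 0)

    def test_masked_sum_conservation(self):
        cube, comp, labeled = self._cube_with_blob((30, 30))
        crop = crop_seed(cube, comp, labeled)
        expected = cube.data[labeled == 1].sum()
        assert np.isclose(crop.patch.sum(), expected)


class TestRgbComposite:
    def test_band_order_and_indices(self):
        wl = np.linspace(400, 1000, 300)
        data = np.tile(wl, (2, 2, 1))
        cube = SpectralCube(data, wl)
        out = rgb_composite(cube)
        assert out.shape == (2, 2, 3)
        # red channel near 642 nm, green near 546, blue near 460
        assert abs(out[0, 0, 0] - 642) < 2
        assert abs(out[0, 0, 1] - 546) < 2
        assert abs(out[0, 0, 2] - 460) < 2

    def test_constant_cube_constant_composite(self):
        wl = np.linspace(400, 1000, 50)
        cube = SpectralCube(np.full((3, 3, 50), 0.4), wl)
        assert np.allclose(rgb_composite(cube), 0.4)


def test_end_to_end_small_scene_recovers_all_seeds(small_scene):
    mask, table = segment_scene(small_scene.vnir, grid_rows=2, grid_cols=2)
    assert len(table) == len(small_scene.truth_components)
    truth = small_scene.truth_mask.astype(bool)
    pred = mask.astype(bool)
    tp = np.sum(truth & pred)
    f1 = 2 * tp / (2 * tp + np.sum(~truth & pred) + np.sum(truth & ~pred))
    assert f1 >= 0.95
    assert set(table["grid_label"]) == set(small_scene.protein_by_seed)
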