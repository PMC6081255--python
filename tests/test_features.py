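"""Unit and property tests for the radiomic feature engine."""

import numpy as np
import pytest

from plaque_radiomics.features import (
    DIRECTIONS_2D,
    FEATURE_CATALOGUE,
    FeatureExtractionError,
    RadiomicsParams,
    discretise,
    extract_features,
    first_order_features,
    glcm_features,
    glcm_matrix,
    glrlm_features,
    glrlm_matrix,
    glszm_features,
    glszm_matrix,
    shape_features,
)

from conftest import random_discretised
from oracles import brute_glcm, brute_runs, brute_zones


def full_mask(arr):
    return np.ones_like(np.asarray(arr), dtype=bool)


# ---------------------------------------------------------------------------
# Discretisation
# ---------------------------------------------------------------------------


class TestDiscretise:
    def test_identity_binning(self):
        img = np.arange(32, dtype=float).reshape(4, 8)
        d = discretise(img, full_mask(img), 32)
        assert sorted(d.labels) == list(range(1, 33))

    def test_constant_image_maps_to_bin_one(self):
        img = np.full((3, 3), 7.0)
        d = discretise(img, full_mask(img), 16)
        assert (d.labels == 1).all()

    def test_two_bin_edge_arithmetic(self):
        img = np.array([[0.0, 10.0, 20.0, 30.0]])
        d = discretise(img, full_mask(img), 2)
        assert list(d.grid[0]) == [1, 1, 2, 2]

    def test_max_value_lands_in_top_bin(self):
        img = np.array([[0.0, 1.0, 2.0, 3.0]])
        d = discretise(img, full_mask(img), 4)
        assert d.grid[0, -1] == 4

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            discretise(np.zeros((2, 2)), np.zeros((2, 2), dtype=bool), 4)


# ---------------------------------------------------------------------------
# First order
# ---------------------------------------------------------------------------


class TestFirstOrder:
    def test_constant_roi(self):
        img = np.full((4, 4), 5.0)
        d = discretise(img, full_mask(img), 8)
        f = first_order_features(d, img)
        assert f["firstorder_Uniformity"] == 1.0
        assert f["firstorder_Entropy"] == 0.0
        assert f["firstorder_StandardDeviation"] == 0.0

    def test_two_level_half_and_half(self):
        img = np.array([[0.0, 0.0, 10.0, 10.0]])
        d = discretise(img, full_mask(img), 2)
        f = first_order_features(d, img)
        assert f["firstorder_Uniformity"] == pytest.approx(0.5)
        assert f["firstorder_Entropy"] == pytest.approx(1.0)

    def test_values_finite_on_random_rois(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            img = rng.normal(size=(6, 6)) * rng.uniform(0.1, 100)
            d = discretise(img, full_mask(img), 16)
            f = first_order_features(d, img)
            assert all(np.isfinite(v) for v in f.values())


# ---------------------------------------------------------------------------
# Shape
# ---------------------------------------------------------------------------


class TestShape:
    def test_single_pixel_volume(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[2, 2] = True
        f = shape_features(mask, pixel_spacing=0.3, slice_thickness=2.0)
        assert f["shape_Volume"] == pytest.approx(0.3 * 0.3 * 2.0)

    def test_line_maximum_inplane_diameter(self):
        mask = np.zeros((3, 13), dtype=bool)
        mask[1, 1:12] = True  # 11 pixels -> 10 gaps x 0.3 mm
        f = shape_features(mask, pixel_spacing=0.3, slice_thickness=2.0)
        assert f["shape_Maximum2DDiameterSlice"] == pytest.approx(3.0)
        assert f["shape_Maximum3DDiameter"] == pytest.approx(np.hypot(3.0, 2.0))

    def test_square_area_and_perimeter(self):
        mask = np.zeros((6, 6), dtype=bool)
        mask[1:5, 1:5] = True  # 4x4 block
        f = shape_features(mask, pixel_spacing=1.0, slice_thickness=1.0)
        assert f["shape_Area"] == pytest.approx(16.0)
        assert f["shape_Perimeter"] == pytest.approx(16.0)
        assert f["shape_Elongation"] == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------


class TestGlcm:
    def test_hand_enumerated_two_by_two(self):
        img = np.array([[1.0, 1.0], [1.0, 2.0]])
        d = discretise(img, full_mask(img), 2)
        f = glcm_features(d, distance=1, directions=((0, 1),))
        assert f["glcm_Entropy"] == pytest.approx(1.5)
        assert f["glcm_Contrast"] == pytest.approx(0.5)
        assert f["glcm_Energy"] == pytest.approx(0.375)
        assert f["glcm_MaximumProbability"] == pytest.approx(0.5)

    def test_constant_roi(self):
        img = np.full((3, 3), 4.0)
        d = discretise(img, full_mask(img), 8)
        f = glcm_features(d)
        assert f["glcm_Entropy"] == pytest.approx(0.0)
        assert f["glcm_Energy"] == pytest.approx(1.0)
        assert f["glcm_Contrast"] == pytest.approx(0.0)
        assert f["glcm_Homogeneity"] == pytest.approx(1.0)
        assert f["glcm_MaximumProbability"] == pytest.approx(1.0)

    def test_checkerboard_contrast(self):
        img = np.indices((4, 4)).sum(axis=0) % 2 * 10.0
        d = discretise(img, full_mask(img), 2)
        f = glcm_features(d, directions=((0, 1),))
        assert f["glcm_Contrast"] == pytest.approx(1.0)
        assert f["glcm_MaximumProbability"] == pytest.approx(0.5)

    def test_single_pixel_roi_undefined(self):
        mask = np.zeros((3, 3), dtype=bool)
        mask[1, 1] = True
        d = discretise(np.ones((3, 3)), mask, 4)
        with pytest.raises(FeatureExtractionError):
            glcm_features(d)

    def test_matrix_symmetry_and_normalisation(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            d = random_discretised(rng)
            for off in DIRECTIONS_2D:
                m = glcm_matrix(d, off)
                assert np.allclose(m, m.T)
                if m.sum() > 0:
                    p = m / m.sum()
                    assert p.sum() == pytest.approx(1.0)

    def test_entropy_bounds(self):
        rng = np.random.default_rng(1)
        for _ in range(25):
            d = random_discretised(rng)
            try:
                f = glcm_features(d)
            except FeatureExtractionError:
                continue
            assert 0.0 <= f["glcm_Entropy"] <= 2 * np.log2(d.n_bins) + 1e-9


# ---------------------------------------------------------------------------
# GLRLM
# ---------------------------------------------------------------------------


class TestGlrlm:
    def test_single_run(self):
        img = np.array([[3.0, 3.0, 3.0]])
        d = discretise(img, full_mask(img), 2)
        f = glrlm_features(d, directions=((0, 1),))
        assert f["glrlm_RunLengthNonUniformity"] == pytest.approx(1.0)
        assert f["glrlm_ShortRunEmphasis"] == pytest.approx(1.0 / 9.0)

    def test_alternating_runs(self):
        img = np.array([[1.0, 2.0, 1.0, 2.0]])
        d = discretise(img, full_mask(img), 2)
        f = glrlm_features(d, directions=((0, 1),))
        # four runs of length 1 -> RLN = 4^2 / 4
        assert f["glrlm_RunLengthNonUniformity"] == pytest.approx(4.0)
        assert f["glrlm_RunPercentage"] == pytest.approx(1.0)

    @pytest.mark.parametrize("n", [2, 5, 8])
    def test_constant_row_short_run_emphasis(self, n):
        img = np.full((1, n), 2.0)
        d = discretise(img, full_mask(img), 2)
        f = glrlm_features(d, directions=((0, 1),))
        assert f["glrlm_ShortRunEmphasis"] == pytest.approx(1.0 / n**2)


# ---------------------------------------------------------------------------
# GLSZM
# ---------------------------------------------------------------------------


class TestGlszm:
    def test_constant_roi_single_zone(self):
        img = np.full((3, 4), 1.0)
        d = discretise(img, full_mask(img), 2)
        f = glszm_features(d)
        assert f["glszm_ZoneEntropy"] == pytest.approx(0.0)
        assert f["glszm_ZonePercentage"] == pytest.approx(1.0 / 12.0)

    def test_two_disjoint_blobs(self):
        grid = np.zeros((5, 9))
        grid[1, 1:4] = 5.0  # 3-pixel blob
        grid[3, 4:9] = 5.0  # 5-pixel blob
        mask = grid > 0
        d = discretise(grid, mask, 2)
        Z = glszm_matrix(d)
        sizes = {s + 1: int(Z[:, s].sum()) for s in range(Z.shape[1]) if Z[:, s].sum()}
        assert sizes == {3: 1, 5: 1}

    def test_all_distinct_levels_give_singleton_zones(self):
        # With 8-connectivity a two-level checkerboard merges diagonally, so
        # the every-zone-is-a-single-pixel case needs pairwise-distinct levels.
        img = np.arange(4, dtype=float).reshape(2, 2)
        d = discretise(img, full_mask(img), 4)
        f = glszm_features(d)
        assert f["glszm_ZonePercentage"] == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# Catalogue contract and invariances
# ---------------------------------------------------------------------------


class TestCatalogue:
    def test_full_catalogue_order_and_finiteness(self):
        rng = np.random.default_rng(2)
        img = rng.normal(size=(12, 12)) * 40 + 100
        mask = np.zeros((12, 12), dtype=bool)
        mask[2:10, 2:10] = True
        f = extract_features(img, mask, RadiomicsParams(n_bins=16))
        assert list(f.keys()) == FEATURE_CATALOGUE
        assert len(f) >= 94
        assert all(np.isfinite(v) for v in f.values())

    def test_intensity_shift_leaves_textures_unchanged(self):
        rng = np.random.default_rng(3)
        img = rng.normal(size=(10, 10)) * 20 + 80
        mask = rng.random((10, 10)) < 0.8
        mask[4:6, 4:6] = True
        base = extract_features(img, mask)
        shifted = extract_features(img + 37.5, mask)
        for k in base:
            if k.split("_")[0] in ("glcm", "glrlm", "glszm"):
                assert shifted[k] == pytest.approx(base[k], abs=1e-10), k

    def test_rotation_consistency_of_direction_averaged_features(self):
        rng = np.random.default_rng(4)
        img = rng.normal(size=(9, 9))
        mask = rng.random((9, 9)) < 0.8
        mask[4, 4] = mask[4, 5] = True
        base = extract_features(img, mask)
        rot = extract_features(np.rot90(img).copy(), np.rot90(mask).copy())
        for k in base:
            fam = k.split("_")[0]
            if fam in ("glcm", "glrlm", "glszm") or k.startswith("firstorder"):
                assert rot[k] == pytest.approx(base[k], abs=1e-9), k


# ---------------------------------------------------------------------------
# Brute-force matrix agreement (smoke; the 500-case suite runs in acceptance)
# ---------------------------------------------------------------------------


class TestBruteForceSmoke:
    def test_matrices_match_enumerators(self):
        rng = np.random.default_rng(6)
        for _ in range(30):
            d = random_discretised(rng)
            for off in DIRECTIONS_2D:
                assert np.array_equal(
                    glcm_matrix(d, off), brute_glcm(d.grid, d.mask, off, d.n_bins)
                )
                R = glrlm_matrix(d, off)
                expected = brute_runs(d.grid, d.mask, off)
                got = {
                    (i + 1, j + 1): int(R[i, j])
                    for i in range(R.shape[0])
                    for j in range(R.shape[1])
                    if R[i, j]
                }
                assert got == dict(expected)
            Z = glszm_matrix(d)
            got_z = {
                (i + 1, s + 1): int(Z[i, s])
                for i in range(Z.shape[0])
                for s in range(Z.shape[1])
                if Z[i, s]
            }
            assert got_z == dict(brute_zones(d.grid, d.mask))
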