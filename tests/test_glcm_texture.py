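import numpy as np
import pytest
from shapely.geometry import box

from canopyhydra.glcm_texture import (
    GlcmConfig,
    cooccurrence,
    glcm_feature_maps,
    quantize,
    region_texture,
    texture_features,
)
from canopyhydra.types import MultispectralScene, PlotRegion

from oracles import naive_cooccurrence, naive_features


class TestQuantize:
    def test_two_values_two_levels(self):
        np.testing.assert_array_equal(quantize([0.0, 1.0], 2), [0, 1])

    def test_constant_maps_to_zero(self):
        np.testing.assert_array_equal(quantize(np.full((3, 3), 0.5), 64), 0)

    def test_four_levels_bin_arithmetic(self):
        np.testing.assert_array_equal(quantize([0.0, 0.25, 0.5, 1.0], 4), [0, 1, 2, 3])

    def test_fixed_range_clips(self):
        np.testing.assert_array_equal(
            quantize([-0.5, 0.0, 0.5, 2.0], 4, value_range=(0.0, 1.0)), [0, 0, 2, 3]
        )

    def test_invalid_levels(self):
        with pytest.raises(ValueError):
            quantize([1.0, 2.0], 1)


class TestCooccurrence:
    def test_two_row_example(self):
        P = cooccurrence(np.array([[0, 0], [1, 1]]), offset=(0, 1), symmetric=True)
        assert P[0, 0] == pytest.approx(0.5)
        assert P[1, 1] == pytest.approx(0.5)
        assert P.sum() == pytest.approx(1.0)

    def test_constant_window_single_cell(self):
        P = cooccurrence(np.zeros((4, 4), dtype=int), offset=(1, 1))
        assert P.shape == (1, 1)
        assert P[0, 0] == pytest.approx(1.0)

    def test_symmetry_on_random_windows(self, rng):
        for _ in range(5):
            w = rng.integers(0, 8, size=(6, 6))
            P = cooccurrence(w, offset=(1, 1), symmetric=True)
            np.testing.assert_allclose(P, P.T, atol=1e-15)

    def test_offset_larger_than_window_rejected(self):
        with pytest.raises(ValueError, match="no valid pairs"):
            cooccurrence(np.array([[0, 1]]), offset=(2, 0))

    def test_float_input_rejected(self):
        with pytest.raises(ValueError, match="integer"):
            cooccurrence(np.array([[0.5, 1.0]]), offset=(0, 1))


class TestTextureFeatures:
    def test_two_row_example_hand_values(self):
        P = cooccurrence(np.array([[0, 0], [1, 1]]), offset=(0, 1), symmetric=True)
        f = texture_features(P)
        assert f["CON"] == pytest.approx(0.0)
        assert f["HOM"] == pytest.approx(1.0)
        assert f["SEM"] == pytest.approx(0.5)
        assert f["ENT"] == pytest.approx(np.log(2))

    def test_constant_window_degenerate_features(self):
        P = cooccurrence(np.zeros((5, 5), dtype=int), offset=(0, 1))
        f = texture_features(P)
        assert f["VAR"] == 0.0
        assert f["CON"] == 0.0
        assert f["DIS"] == 0.0
        assert f["HOM"] == 1.0
        assert f["SEM"] == 1.0
        assert f["ENT"] == 0.0
        assert f["COR"] == 0.0  # sentinel: undefined for zero variance

    def test_checkerboard_contrast(self):
        w = np.indices((6, 6)).sum(axis=0) % 2
        P = cooccurrence(w, offset=(0, 1), symmetric=True)
        f = texture_features(P)
        assert P[0, 0] == 0.0 and P[1, 1] == 0.0  # all mass off-diagonal
        assert f["CON"] == pytest.approx(1.0)
        assert f["DIS"] == pytest.approx(1.0)

    def test_unnormalized_input_rejected(self):
        with pytest.raises(ValueError, match="normalized"):
            texture_features(np.ones((2, 2)))


class TestOracleEquivalence:
    @pytest.mark.parametrize("offset", [(0, 1), (1, 0), (1, 1)])
    @pytest.mark.parametrize("symmetric", [True, False])
    def test_matches_pair_enumeration_oracle(self, rng, offset, symmetric):
        for _ in range(8):
            w = rng.integers(0, 6, size=(9, 9))
            P = cooccurrence(w, offset=offset, symmetric=symmetric, levels=6)
            P_oracle = naive_cooccurrence(w, offset, symmetric, levels=6)
            np.testing.assert_allclose(P, P_oracle, atol=1e-12)
            f = texture_features(P)
            f_oracle = naive_features(P_oracle)
            for k in f:
                assert f[k] == pytest.approx(f_oracle[k], abs=1e-12), k

    def test_matches_scikit_image_graycomatrix(self, rng):
        """Cross-check the co-occurrence counts against scikit-image."""
        from skimage.feature import graycomatrix

        w = rng.integers(0, 8, size=(12, 12)).astype(np.uint8)
        ours = cooccurrence(w, offset=(0, 1), symmetric=True, levels=8)
        theirs = graycomatrix(w, [1], [0], levels=8, symmetric=True, normed=True)
        np.testing.assert_allclose(ours, theirs[:, :, 0, 0], atol=1e-12)


class TestInvariances:
    def test_gray_level_shift_leaves_shape_features_unchanged(self, rng):
        w = rng.integers(0, 10, size=(8, 8))
        f1 = texture_features(cooccurrence(w, offset=(1, 1), levels=20))
        f2 = texture_features(cooccurrence(w + 5, offset=(1, 1), levels=20))
        for k in ("CON", "DIS", "HOM", "ENT", "SEM"):
            assert f1[k] == pytest.approx(f2[k], abs=1e-12), k
        assert f2["MEA"] == pytest.approx(f1["MEA"] + 5, abs=1e-12)

    def test_normalization_on_random_inputs(self, rng):
        for _ in range(10):
            w = rng.integers(0, 16, size=(7, 7))
            P = cooccurrence(w, offset=(1, 1))
            assert P.sum() == pytest.approx(1.0, abs=1e-12)


def _one_band_scene(patch: np.ndarray) -> tuple[MultispectralScene, PlotRegion]:
    bands = np.repeat(patch[None, :, :], 6, axis=0)
    region = PlotRegion("P01", box(0, 0, patch.shape[1], patch.shape[0]))
    return MultispectralScene(bands=bands, plots=[region]), region


class TestRegionTexture:
    def test_constant_region_degenerate_vector(self):
        scene, region = _one_band_scene(np.full((12, 12), 0.4))
        vec = region_texture(scene, region)
        per_band = vec.reshape(6, 8)
        np.testing.assert_allclose(per_band[:, 1], 0.0)  # VAR
        np.testing.assert_allclose(per_band[:, 2], 1.0)  # HOM
        np.testing.assert_allclose(per_band[:, 6], 1.0)  # SEM

    def test_region_smaller_than_window_rejected(self):
        scene, region = _one_band_scene(np.full((5, 5), 0.4))
        with pytest.raises(ValueError, match="P01"):
            region_texture(scene, region)

    def test_regional_average_matches_explicit_window_mean(self, rng):
        patch = rng.uniform(0.2, 0.6, size=(11, 11))
        scene, region = _one_band_scene(patch)
        cfg = GlcmConfig(quantization="region")
        vec = region_texture(scene, region, cfg)
        maps, valid, cor_def = glcm_feature_maps(patch, cfg)
        assert vec[0] == pytest.approx(np.nanmean(maps[0][valid]))
        assert vec[3] == pytest.approx(np.nanmean(maps[3][valid]))

    def test_scene_vs_region_quantization_differ(self, rng):
        patch = rng.uniform(0.30, 0.35, size=(11, 11))
        bands = np.repeat(patch[None, :, :], 6, axis=0)
        bands[:, 0, 0] = 0.9  # background pixel widens the scene range
        region = PlotRegion("P01", box(1, 1, 11, 11))
        scene = MultispectralScene(bands=bands, plots=[region])
        v_scene = region_texture(scene, region, GlcmConfig(quantization="scene"))
        v_region = region_texture(scene, region, GlcmConfig(quantization="region"))
        assert not np.allclose(v_scene, v_region)
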