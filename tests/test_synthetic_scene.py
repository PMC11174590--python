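import numpy as np
import pandas as pd
import pytest
from scipy import stats

from canopyhydra.synthetic_scene import (
    draw_moisture,
    generate_design,
    planted_texture_table,
    render_scene,
    simulate,
    write_scene,
)
from canopyhydra.types import SceneConfig, TreatmentDesign


class TestGenerateDesign:
    def test_default_design_yields_54_samples(self):
        rows = generate_design(TreatmentDesign(), seed=0)
        assert len(rows) == 54
        assert rows["season"].nunique() == 2
        per_season = rows[rows.season == 1]
        assert len(per_season) == 27
        counts = per_season.groupby(["mulch", "irrigation"]).size()
        assert (counts == 3).all()

    def test_identity_case(self):
        d = TreatmentDesign(("NM",), ("W1",), replicates=1, seasons=1)
        assert len(generate_design(d, seed=0)) == 1

    def test_level_product(self):
        d = TreatmentDesign(("SM", "FM"), ("W1", "W2", "W3"), replicates=2, seasons=1)
        assert len(generate_design(d, seed=0)) == 12

    def test_zero_levels_rejected(self):
        with pytest.raises(ValueError):
            TreatmentDesign(mulch_levels=(), irrigation_levels=("W1",))
        with pytest.raises(ValueError):
            TreatmentDesign(replicates=0)

    def test_same_layout_both_seasons_and_determinism(self):
        a = generate_design(TreatmentDesign(), seed=5)
        b = generate_design(TreatmentDesign(), seed=5)
        pd.testing.assert_frame_equal(a, b)
        s1 = a[a.season == 1].set_index("plot_id")[["mulch", "irrigation"]]
        s2 = a[a.season == 2].set_index("plot_id")[["mulch", "irrigation"]]
        pd.testing.assert_frame_equal(s1, s2)


class TestDrawMoisture:
    def test_degenerate_noise_gives_baseline(self):
        cfg = SceneConfig(
            moisture_sd_pct=0.0,
            mulch_effects_pct={"SM": 0, "FM": 0, "NM": 0},
            irrigation_effects_pct={"W1": 0, "W2": 0, "W3": 0},
        )
        rows = generate_design(TreatmentDesign(), seed=0)
        np.testing.assert_allclose(draw_moisture(rows, cfg), 70.0)

    def test_additive_irrigation_effect_exact(self):
        cfg = SceneConfig(
            moisture_sd_pct=0.0,
            mulch_effects_pct={"SM": 0, "FM": 0, "NM": 0},
            irrigation_effects_pct={"W1": 0, "W2": 0, "W3": 4.0},
        )
        rows = generate_design(TreatmentDesign(), seed=0)
        m = draw_moisture(rows, cfg)
        w3 = rows["irrigation"] == "W3"
        np.testing.assert_allclose(m[w3], 74.0)
        np.testing.assert_allclose(m[~w3], 70.0)

    def test_sample_mean_clt_bound(self):
        n = 10_000
        rows = pd.DataFrame({"mulch": ["NM"] * n, "irrigation": ["W1"] * n})
        cfg = SceneConfig(
            moisture_sd_pct=2.0,
            mulch_effects_pct={"NM": 0},
            irrigation_effects_pct={"W1": 0},
            seed=123,
        )
        m = draw_moisture(rows, cfg)
        assert abs(m.mean() - 70.0) < 3 * 2.0 / np.sqrt(n)

    def test_unknown_treatment_level_rejected(self):
        rows = pd.DataFrame({"mulch": ["XX"], "irrigation": ["W1"]})
        with pytest.raises(ValueError, match="without configured effects"):
            draw_moisture(rows, SceneConfig())


class TestRenderScene:
    def test_zero_slope_zero_noise_constant_plots(self, small_design):
        cfg = SceneConfig(
            plot_size_px=(10, 10),
            band_slopes=(0.0,) * 6,
            texture_link=0.0,
            noise_sd=0.0,
            plot_noise_sd=0.0,
            moisture_sd_pct=0.0,
        )
        rows = generate_design(small_design, seed=0)
        scene = render_scene(rows, draw_moisture(rows, cfg), cfg)
        (r0, r1, c0, c1), inside = scene.plots[0].pixel_mask(scene.shape)
        patch = scene.bands[5, r0:r1, c0:c1][inside]
        assert np.ptp(patch) == 0.0

    def test_wetter_plot_brighter_nir(self):
        cfg = SceneConfig(plot_size_px=(10, 10), noise_sd=0.0, plot_noise_sd=0.0,
                          texture_link=0.0)
        rows = pd.DataFrame(
            {"plot_id": ["P01", "P02"], "season": [1, 1], "mulch": ["NM"] * 2,
             "irrigation": ["W1"] * 2}
        )
        scene = render_scene(rows, np.array([60.0, 80.0]), cfg)
        from canopyhydra.raster_io import mean_reflectance

        dry = mean_reflectance(scene, scene.plots[0], 6)
        wet = mean_reflectance(scene, scene.plots[1], 6)
        assert wet > dry

    def test_texture_variance_grows_with_moisture(self):
        cfg = SceneConfig(plot_size_px=(16, 16), noise_sd=0.0, plot_noise_sd=0.0,
                          texture_link=0.01, seed=4)
        n = 20
        rows = pd.DataFrame(
            {"plot_id": [f"P{k:02d}" for k in range(n)], "season": [1] * n,
             "mulch": ["NM"] * n, "irrigation": ["W1"] * n}
        )
        moisture = np.linspace(40, 95, n)
        scene = render_scene(rows, moisture, cfg)
        variances = []
        for plot in scene.plots:
            (r0, r1, c0, c1), inside = plot.pixel_mask(scene.shape)
            variances.append(scene.bands[5, r0:r1, c0:c1][inside].var())
        rho = stats.spearmanr(moisture, variances).statistic
        assert rho > 0

    def test_reflectance_fully_outside_unit_interval_rejected(self):
        cfg = SceneConfig(band_intercepts=(2.0,) * 6, band_slopes=(0.5,) * 6)
        rows = pd.DataFrame({"plot_id": ["P01"], "season": [1], "mulch": ["NM"],
                             "irrigation": ["W1"]})
        with pytest.raises(ValueError, match="outside"):
            render_scene(rows, np.array([70.0]), cfg)

    def test_determinism_bit_identical(self, small_design, small_scene_config):
        s1, t1 = simulate(small_design, small_scene_config)
        s2, t2 = simulate(small_design, small_scene_config)
        np.testing.assert_array_equal(s1.bands, s2.bands)
        pd.testing.assert_frame_equal(t1, t2)


class TestPlantedSignal:
    def test_nir_mean_correlation_approaches_one_without_noise(self):
        cfg = SceneConfig(plot_size_px=(12, 12), noise_sd=0.0, plot_noise_sd=0.0,
                          texture_link=0.0, seed=9)
        rows = generate_design(TreatmentDesign(seasons=1), seed=9)
        moisture = draw_moisture(rows, cfg)
        scene = render_scene(rows, moisture, cfg)
        from canopyhydra.raster_io import mean_reflectance

        nir = [mean_reflectance(scene, p, 6) for p in scene.plots]
        r = stats.pearsonr(nir, moisture).statistic
        assert r > 0.999


class TestWriteScene:
    def test_round_trip_float32(self, small_scene, tmp_path):
        from canopyhydra.raster_io import read_scene

        scene, table = small_scene
        paths = write_scene(scene, table, tmp_path / "out")
        back = read_scene(paths["raster"], paths["regions"])
        np.testing.assert_array_equal(back.bands, scene.bands.astype(np.float32))
        assert len(back.plots) == len(scene.plots)
        t2 = pd.read_csv(paths["moisture"])
        np.testing.assert_allclose(t2["moisture_pct"], table["moisture_pct"])


class TestPlantedTextureTable:
    def test_deterministic_and_shaped(self):
        t1, m1 = planted_texture_table(seed=5)
        t2, m2 = planted_texture_table(seed=5)
        pd.testing.assert_frame_equal(t1, t2)
        np.testing.assert_array_equal(m1, m2)
        assert t1.shape == (54, 48)

    def test_planted_index_strongly_correlated(self):
        from canopyhydra.texture_index_search import texture_index

        table, m = planted_texture_table(seed=2)
        idx = texture_index("RDTI", table["Variance1"], table["Correlation5"])
        assert abs(stats.pearsonr(idx, m).statistic) > 0.9
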