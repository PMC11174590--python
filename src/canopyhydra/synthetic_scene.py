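"""Synthetic multiband canopy scenes with a planted moisture signal.

The generator emulates a two-season split-plot field trial: three mulch
levels crossed with three supplementary-irrigation levels, three
replicates, 27 plots per season, 54 plot-season samples.  Each sample
receives a leaf moisture value (percent of fresh mass) from an additive
treatment-effect model with Gaussian noise; each plot is rendered as a
rectangular patch in a six-band reflectance raster where

* the plot's mean reflectance in band b is an affine function of its
  moisture (negative slopes in the visible, positive in the red edge and
  NIR — the usual well-watered-canopy direction), and
* within-plot spatial variability is kernel-smoothed Gaussian noise whose
  variance grows linearly with moisture, so co-occurrence texture features
  also carry the moisture signal.

This is deliberately the simplest texture-bearing model: real canopy
structure (rows, leaves, shadows, soil gaps) is out of scope.  A separate
table-level generator, :func:`planted_texture_table`, plants a known
feature *pair* for exercising the texture-index search.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage
from shapely.geometry import box, mapping

from .types import (
    TEXTURE_FEATURE_NAMES,
    MultispectralScene,
    PlotRegion,
    SceneConfig,
    TreatmentDesign,
)

__all__ = [
    "generate_design",
    "draw_moisture",
    "render_scene",
    "write_scene",
    "simulate",
    "planted_texture_table",
]

_MOISTURE_EPS = 0.1  # clamp margin keeping moisture strictly inside (0, 100)


def generate_design(
    design: TreatmentDesign = TreatmentDesign(), seed: int | None = 0
) -> pd.DataFrame:
    """Enumerate plot-season rows with randomized treatment-to-plot layout.

    Returns a DataFrame with columns plot_id, season, mulch, irrigation.
    Plot ids P01.. are fixed positions; which treatment a plot carries is
    shuffled once (the same layout in both seasons, as in a real trial),
    deterministically per seed.
    """
    rng = np.random.default_rng(seed)
    treatments = [
        (m, w)
        for m in design.mulch_levels
        for w in design.irrigation_levels
        for _ in range(design.replicates)
    ]
    order = rng.permutation(len(treatments))
    rows = []
    for season in range(1, design.seasons + 1):
        for pos, t_idx in enumerate(order):
            m, w = treatments[t_idx]
            rows.append(
                {
                    "plot_id": f"P{pos + 1:02d}",
                    "season": season,
                    "mulch": m,
                    "irrigation": w,
                }
            )
    return pd.DataFrame(rows)


def draw_moisture(rows: pd.DataFrame, config: SceneConfig) -> np.ndarray:
    """Leaf moisture (%) per design row: baseline + effects + noise.

    moisture = moisture_mean_pct + mulch effect + irrigation effect
               + N(0, moisture_sd_pct), clamped just inside (0, 100).
    Deterministic for a fixed ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    mulch_eff = rows["mulch"].map(config.mulch_effects_pct)
    irr_eff = rows["irrigation"].map(config.irrigation_effects_pct)
    if mulch_eff.isna().any() or irr_eff.isna().any():
        raise ValueError("design contains treatment levels without configured effects")
    m = (
        config.moisture_mean_pct
        + mulch_eff.to_numpy(dtype=float)
        + irr_eff.to_numpy(dtype=float)
        + rng.normal(0.0, config.moisture_sd_pct, size=len(rows))
    )
    return np.clip(m, _MOISTURE_EPS, 100.0 - _MOISTURE_EPS)


def _plot_grid(n_plots: int) -> tuple[int, int]:
    """Near-square grid layout (rows, cols) for n plot patches."""
    cols = int(np.ceil(np.sqrt(n_plots * 1.5)))
    rows = int(np.ceil(n_plots / cols))
    return rows, cols


def render_scene(
    rows: pd.DataFrame, moisture: np.ndarray, config: SceneConfig
) -> MultispectralScene:
    """Render design rows into a six-band raster with one patch per sample.

    Each plot-season row becomes one rectangular region.  Band means follow
    the affine moisture link; within-plot variability is smoothed Gaussian
    noise with moisture-linked variance plus white sensor noise; all values
    are clamped to [0, 1].  Deterministic per ``config.seed``.
    """
    if len(rows) == 0:
        raise ValueError("no design rows to render")
    moisture = np.asarray(moisture, dtype=float)
    if moisture.shape != (len(rows),):
        raise ValueError("moisture length must match the number of rows")
    intercepts = np.asarray(config.band_intercepts)
    slopes = np.asarray(config.band_slopes)
    means = intercepts[None, :] + slopes[None, :] * moisture[:, None]
    if np.any(np.all((means < 0) | (means > 1), axis=1)):
        raise ValueError(
            "band response places a plot's reflectance entirely outside [0, 1]"
        )
    means = np.clip(means, 0.0, 1.0)

    ph, pw = config.plot_size_px
    g = config.gutter_px
    grid_r, grid_c = _plot_grid(len(rows))
    H = grid_r * (ph + g) + g
    W = grid_c * (pw + g) + g
    bands = np.full((6, H, W), config.background_reflectance, dtype=np.float64)
    rng = np.random.default_rng(config.seed + 1)

    regions: list[PlotRegion] = []
    for k, (_, row) in enumerate(rows.iterrows()):
        gr, gc = divmod(k, grid_c)
        r0 = g + gr * (ph + g)
        c0 = g + gc * (pw + g)
        target_var = config.texture_link * moisture[k] / 100.0
        for b in range(6):
            mean_b = means[k, b]
            if config.plot_noise_sd > 0:
                mean_b = np.clip(
                    mean_b + rng.normal(0.0, config.plot_noise_sd), 0.0, 1.0
                )
            patch = np.full((ph, pw), mean_b)
            if target_var > 0:
                field = ndimage.gaussian_filter(
                    rng.standard_normal((ph, pw)), config.texture_smooth_sigma,
                    mode="reflect",
                )
                field -= field.mean()  # texture must not shift the plot mean
                sd = field.std()
                if sd > 0:
                    patch += field / sd * np.sqrt(target_var)
            if config.noise_sd > 0:
                patch += rng.normal(0.0, config.noise_sd, size=(ph, pw))
            bands[b, r0 : r0 + ph, c0 : c0 + pw] = np.clip(patch, 0.0, 1.0)
        regions.append(
            PlotRegion(
                plot_id=str(row["plot_id"]),
                season=int(row["season"]),
                polygon=box(c0, r0, c0 + pw, r0 + ph),
            )
        )
    return MultispectralScene(bands=bands.astype(np.float32), plots=regions)


def simulate(
    design: TreatmentDesign = TreatmentDesign(), config: SceneConfig = SceneConfig()
) -> tuple[MultispectralScene, pd.DataFrame]:
    """Design -> moisture -> scene; returns the scene and the moisture table."""
    rows = generate_design(design, seed=config.seed)
    moisture = draw_moisture(rows, config)
    scene = render_scene(rows, moisture, config)
    table = rows.copy()
    table["moisture_pct"] = moisture
    return scene, table


def write_scene(scene: MultispectralScene, table: pd.DataFrame, out_dir) -> dict[str, Path]:
    """Serialize a scene to ``out_dir``: scene.tif, plots.geojson, moisture.csv.

    The raster is a float32 multiband TIFF (band order 1..6); regions are a
    GeoJSON FeatureCollection in raster coordinates keyed by plot_id and
    season.  Round-tripping through :func:`canopyhydra.raster_io.read_scene`
    reproduces values to float32 precision.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "raster": out / "scene.tif",
            "regions": out / "plots.geojson",
            "moisture": out / "moisture.csv",
        }
        tifffile.imwrite(
            paths["raster"],
            scene.bands.astype(np.float32),
            photometric="minisblack",
            metadata={"wavelengths_nm": list(scene.wavelengths_nm)},
        )
        features = [
            {
                "type": "Feature",
                "geometry": mapping(p.polygon),
                "properties": {"plot_id": p.plot_id, "season": p.season},
            }
            for p in scene.plots
        ]
        paths["regions"].write_text(
            json.dumps({"type": "FeatureCollection", "features": features}, indent=1)
        )
        table.to_csv(paths["moisture"], index=False)
    except OSError as exc:
        raise OSError(f"failed writing scene to {out}: {exc}") from exc
    return paths


def planted_texture_table(
    n: int = 54,
    pair: tuple[str, str] = ("Variance1", "Correlation5"),
    family: str = "RDTI",
    effect_pct: float = 3.0,
    noise_sd_pct: float = 0.8,
    baseline_pct: float = 70.0,
    seed: int | None = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """A 48-feature texture table where one designated pair drives moisture.

    Features are drawn i.i.d. uniform on [0.5, 2.5] (positive, so all six
    index families are defined everywhere); moisture is

        baseline + effect * z(index(family, T_i, T_j)) + N(0, noise_sd),

    with z the standardization of the planted pair's index.  Used to check
    that the exhaustive search recovers a known signal.
    """
    from .texture_index_search import texture_index

    rng = np.random.default_rng(seed)
    table = pd.DataFrame(
        rng.uniform(0.5, 2.5, size=(n, len(TEXTURE_FEATURE_NAMES))),
        columns=list(TEXTURE_FEATURE_NAMES),
    )
    for f in pair:
        if f not in table.columns:
            raise KeyError(f"unknown texture feature {f!r}")
    idx = texture_index(family, table[pair[0]], table[pair[1]])
    z = (idx - idx.mean()) / idx.std()
    moisture = baseline_pct + effect_pct * z + rng.normal(0, noise_sd_pct, size=n)
    return table, np.clip(moisture, _MOISTURE_EPS, 100 - _MOISTURE_EPS)
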