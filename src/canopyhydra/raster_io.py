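"""Raster and region I/O plus per-plot mean reflectance extraction.

Rasters are multiband float TIFFs (band order 1..6); plot regions are
GeoJSON polygons in raster coordinates (x = column, y = row).  A pixel
belongs to a region when its center lies inside the polygon — the
half-open convention documented in :mod:`canopyhydra.types`; edge pixel
counts depend on this rule, so it is fixed here rather than configurable.

Shadow/soil exclusion, which field workflows do by hand, is exposed as an
optional NIR-floor threshold mask (pixels whose NIR reflectance falls
below the floor are excluded); it is off by default.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from shapely.geometry import shape as shapely_shape

from .types import WAVELENGTHS_NM, MultispectralScene, PlotRegion

__all__ = [
    "read_scene",
    "read_regions",
    "mean_reflectance",
    "extract_samples",
    "nir_floor_mask",
    "reflectance_table",
]


def read_regions(regions_path) -> list[PlotRegion]:
    """Load plot regions from a GeoJSON FeatureCollection."""
    path = Path(regions_path)
    if not path.exists():
        raise FileNotFoundError(f"regions file not found: {path}")
    payload = json.loads(path.read_text())
    regions = []
    for feat in payload.get("features", []):
        props = feat.get("properties", {})
        if "plot_id" not in props:
            raise ValueError(f"{path}: feature missing plot_id property")
        regions.append(
            PlotRegion(
                plot_id=str(props["plot_id"]),
                season=int(props.get("season", 1)),
                polygon=shapely_shape(feat["geometry"]),
            )
        )
    if not regions:
        raise ValueError(f"{path}: no regions found")
    return regions


def read_scene(raster_path, regions_path, expected_bands: int | None = 6) -> MultispectralScene:
    """Read a multiband TIFF and its GeoJSON regions into a scene.

    Bands are returned in file order.  Raises distinct errors for a missing
    file, an unexpected band count, and a region outside the raster.
    """
    path = Path(raster_path)
    if not path.exists():
        raise FileNotFoundError(f"raster file not found: {path}")
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None, :, :]
    if arr.ndim != 3:
        raise ValueError(f"{path}: expected a (bands, rows, cols) raster, got shape {arr.shape}")
    # tifffile may return (rows, cols, bands) for interleaved files
    if arr.shape[0] > arr.shape[2]:
        arr = np.moveaxis(arr, -1, 0)
    if expected_bands is not None and arr.shape[0] != expected_bands:
        raise ValueError(
            f"{path}: expected {expected_bands} bands, found {arr.shape[0]}"
        )
    regions = read_regions(regions_path)
    keys = [r.key for r in regions]
    if len(keys) != len(set(keys)):
        raise ValueError(f"{regions_path}: duplicate (plot_id, season) region keys")
    wavelengths = WAVELENGTHS_NM if arr.shape[0] == 6 else tuple(range(arr.shape[0]))
    return MultispectralScene(bands=arr, plots=regions, wavelengths_nm=wavelengths)


def mean_reflectance(scene: MultispectralScene, region: PlotRegion, band: int) -> float:
    """Arithmetic mean reflectance of one band over a region's pixels.

    ``band`` is 1-based.  Masked-out pixels never contribute; an empty
    region after masking is an explicit error, never a silent zero.
    """
    if not 1 <= band <= scene.n_bands:
        raise ValueError(f"band {band} out of range 1..{scene.n_bands}")
    (r0, r1, c0, c1), inside = region.pixel_mask(scene.shape)
    if not inside.any():
        raise ValueError(
            f"region {region.plot_id} (season {region.season}) has no unmasked pixels"
        )
    return float(scene.bands[band - 1, r0:r1, c0:c1][inside].mean())


def nir_floor_mask(scene: MultispectralScene, region: PlotRegion, floor: float,
                   nir_band: int = 6) -> np.ndarray:
    """Exclusion mask (True = excluded) for pixels below a NIR reflectance floor."""
    (r0, r1, c0, c1), _ = region.pixel_mask(scene.shape)
    return scene.bands[nir_band - 1, r0:r1, c0:c1] < floor


def reflectance_table(scene: MultispectralScene) -> pd.DataFrame:
    """Per-plot mean reflectance for all bands: plot_id, season, b1..b6."""
    rows = []
    for region in scene.plots:
        row = {"plot_id": region.plot_id, "season": region.season}
        row.update(
            {f"b{b}": mean_reflectance(scene, region, b) for b in range(1, scene.n_bands + 1)}
        )
        rows.append(row)
    return pd.DataFrame(rows)


def extract_samples(scene: MultispectralScene, moisture_table: pd.DataFrame) -> pd.DataFrame:
    """Join the moisture table with per-plot mean reflectance.

    One output row per moisture-table row (order preserved), with columns
    plot_id, season, any treatment columns, moisture_pct, and b1..b6.
    Unmatched plot ids raise an error listing them.
    """
    required = {"plot_id", "season", "moisture_pct"}
    missing = required - set(moisture_table.columns)
    if missing:
        raise ValueError(f"moisture table missing columns: {sorted(missing)}")
    refl = reflectance_table(scene)
    merged = moisture_table.merge(refl, on=["plot_id", "season"], how="left", sort=False)
    band_cols = [c for c in merged.columns if c.startswith("b")]
    unmatched = merged.loc[merged[band_cols].isna().any(axis=1), ["plot_id", "season"]]
    if len(unmatched):
        ids = [f"{p}/{s}" for p, s in unmatched.itertuples(index=False)]
        raise ValueError(f"no region found for plot-season: {', '.join(ids)}")
    return merged
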