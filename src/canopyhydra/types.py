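"""Core domain containers shared across the pipeline.

Raster convention: arrays are indexed ``[row, col]`` with the origin at the
top-left.  Polygon coordinates are in raster units with ``x = col`` and
``y = row``; a pixel ``(r, c)`` belongs to a region iff its *center*
``(c + 0.5, r + 0.5)`` lies strictly inside the polygon (half-open
convention, so an axis-aligned rectangle from (c0, r0) to (c1, r1) covers
columns ``c0 .. c1-1`` and rows ``r0 .. r1-1``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import shapely
from shapely.geometry import Polygon

__all__ = [
    "WAVELENGTHS_NM",
    "TEXTURE_MEASURES",
    "TEXTURE_FEATURE_NAMES",
    "TreatmentDesign",
    "SceneConfig",
    "PlotRegion",
    "MultispectralScene",
    "PlotSample",
]

#: Band-center wavelengths, band 1..6 (blue, green, red, red edge 1,
#: red edge 2, near infrared).  The red center is nominal metadata only.
WAVELENGTHS_NM = (450, 555, 660, 720, 750, 840)

#: The eight co-occurrence measures, in canonical order.
TEXTURE_MEASURES = (
    "Mean",
    "Variance",
    "Homogeneity",
    "Contrast",
    "Dissimilarity",
    "Entropy",
    "Second Moment",
    "Correlation",
)

#: The 48 texture-feature column names in band-major order:
#: Mean1 .. Correlation1, Mean2 .. Correlation6.
TEXTURE_FEATURE_NAMES = tuple(
    f"{m}{band}" for band in range(1, 7) for m in TEXTURE_MEASURES
)


@dataclass(frozen=True)
class TreatmentDesign:
    """Split-plot mulch x irrigation design replicated over seasons.

    Defaults encode three mulch levels (straw SM, ridge-film FM, none NM)
    crossed with three supplementary-irrigation schedules (W1, W2, W3),
    three replicates, two seasons: 27 plots per season, 54 plot-season
    samples.
    """

    mulch_levels: tuple[str, ...] = ("SM", "FM", "NM")
    irrigation_levels: tuple[str, ...] = ("W1", "W2", "W3")
    replicates: int = 3
    seasons: int = 2

    def __post_init__(self) -> None:
        if not self.mulch_levels or not self.irrigation_levels:
            raise ValueError("mulch and irrigation levels must be non-empty")
        if self.replicates < 1 or self.seasons < 1:
            raise ValueError("replicates and seasons must be positive")

    @property
    def plots_per_season(self) -> int:
        return len(self.mulch_levels) * len(self.irrigation_levels) * self.replicates

    @property
    def n_samples(self) -> int:
        return self.plots_per_season * self.seasons


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of the synthetic multiband scene generator.

    moisture model
        moisture = baseline + mulch effect + irrigation effect + N(0, sd),
        clamped to (0, 100), in percent of fresh mass.
    reflectance model
        plot mean in band b = band_intercepts[b] + band_slopes[b] * moisture
        + N(0, plot_noise_sd), clamped to [0, 1].  The plot-level noise
        term models plot-to-plot canopy variability (density, background)
        that is unrelated to leaf moisture and does not average away over
        pixels; it is what keeps the moisture signal realistically partial.
    texture model
        within-plot spatial variability is kernel-smoothed Gaussian noise,
        mean-centered within the plot so it cannot shift the plot mean,
        with variance ``texture_link * moisture / 100``; plus white sensor
        noise of standard deviation ``noise_sd`` per pixel.
    """

    plot_size_px: tuple[int, int] = (24, 24)
    moisture_mean_pct: float = 70.0
    moisture_sd_pct: float = 2.0
    mulch_effects_pct: dict = field(
        default_factory=lambda: {"SM": 1.5, "FM": 2.5, "NM": 0.0}
    )
    irrigation_effects_pct: dict = field(
        default_factory=lambda: {"W1": 0.0, "W2": 1.5, "W3": 3.0}
    )
    band_intercepts: tuple[float, ...] = (0.075, 0.045, 0.106, 0.110, 0.140, 0.170)
    band_slopes: tuple[float, ...] = (-0.0005, 0.0005, -0.0008, 0.002, 0.003, 0.004)
    texture_link: float = 0.002
    texture_smooth_sigma: float = 1.0
    plot_noise_sd: float = 0.003
    noise_sd: float = 0.005
    gutter_px: int = 4
    background_reflectance: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        rows, cols = self.plot_size_px
        if rows < 1 or cols < 1:
            raise ValueError("plot_size_px must be positive")
        if self.moisture_sd_pct < 0:
            raise ValueError("moisture_sd_pct must be >= 0")
        if not 0 < self.moisture_mean_pct < 100:
            raise ValueError("moisture_mean_pct must lie in (0, 100)")
        if len(self.band_intercepts) != 6 or len(self.band_slopes) != 6:
            raise ValueError("band_intercepts and band_slopes must have 6 entries")
        if self.texture_link < 0 or self.noise_sd < 0 or self.plot_noise_sd < 0:
            raise ValueError("noise parameters must be >= 0")


@dataclass
class PlotRegion:
    """A plot's region of interest in raster coordinates."""

    plot_id: str
    polygon: Polygon
    season: int = 1
    mask: Optional[np.ndarray] = None  # True = excluded, over the bounding window

    def __post_init__(self) -> None:
        if self.polygon.area <= 0:
            raise ValueError(f"region {self.plot_id}: polygon area must be > 0")

    @property
    def key(self) -> tuple[str, int]:
        return (self.plot_id, self.season)

    def bounding_window(self, shape: tuple[int, int]) -> tuple[int, int, int, int]:
        """(r0, r1, c0, c1) of the pixel bounding box, clipped to ``shape``."""
        minx, miny, maxx, maxy = self.polygon.bounds
        r0 = max(int(np.floor(miny)), 0)
        c0 = max(int(np.floor(minx)), 0)
        r1 = min(int(np.ceil(maxy)), shape[0])
        c1 = min(int(np.ceil(maxx)), shape[1])
        if r1 <= r0 or c1 <= c0:
            raise ValueError(f"region {self.plot_id} lies outside the raster")
        return r0, r1, c0, c1

    def pixel_mask(self, shape: tuple[int, int]) -> tuple[tuple[int, int, int, int], np.ndarray]:
        """Boolean inclusion mask over the bounding window.

        Returns the window ``(r0, r1, c0, c1)`` and a (r1-r0, c1-c0) array
        that is True where the pixel center falls inside the polygon and the
        pixel is not excluded by :attr:`mask`.
        """
        r0, r1, c0, c1 = self.bounding_window(shape)
        rr, cc = np.mgrid[r0:r1, c0:c1]
        inside = shapely.contains_xy(self.polygon, cc + 0.5, rr + 0.5)
        if self.mask is not None:
            excl = np.asarray(self.mask, dtype=bool)
            if excl.shape != inside.shape:
                raise ValueError(
                    f"region {self.plot_id}: mask shape {excl.shape} does not match "
                    f"bounding window {inside.shape}"
                )
            inside &= ~excl
        return (r0, r1, c0, c1), inside


@dataclass
class MultispectralScene:
    """A six-band reflectance raster plus its plot regions."""

    bands: np.ndarray  # (n_bands, rows, cols), float, reflectance in [0, 1]
    plots: list[PlotRegion]
    wavelengths_nm: tuple[int, ...] = WAVELENGTHS_NM

    def __post_init__(self) -> None:
        self.bands = np.asarray(self.bands, dtype=np.float32)
        if self.bands.ndim != 3:
            raise ValueError("bands must be a (n_bands, rows, cols) array")
        ids = [p.key for p in self.plots]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate (plot_id, season) keys among regions")
        shape = self.bands.shape[1:]
        for p in self.plots:
            p.bounding_window(shape)  # raises if outside

    @property
    def n_bands(self) -> int:
        return self.bands.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.bands.shape[1:]


@dataclass
class PlotSample:
    """One plot-season record: treatments, moisture, and image features."""

    plot_id: str
    season: int
    mulch: str
    irrigation: str
    moisture_pct: float
    reflectance: Optional[np.ndarray] = None  # (6,), band order 1..6
    texture: Optional[np.ndarray] = None  # (48,), band-major

    def __post_init__(self) -> None:
        if not 0 < self.moisture_pct < 100:
            raise ValueError(
                f"{self.plot_id}/{self.season}: moisture_pct must lie in (0, 100)"
            )
        if self.reflectance is not None:
            self.reflectance = np.asarray(self.reflectance, dtype=float)
            if self.reflectance.shape != (6,):
                raise ValueError("reflectance must be a 6-vector")
        if self.texture is not None:
            self.texture = np.asarray(self.texture, dtype=float)
            if self.texture.shape != (48,):
                raise ValueError("texture must be a 48-vector (8 measures x 6 bands)")


def samples_to_frame(samples: Sequence[PlotSample]) -> "pd.DataFrame":
    """Tabulate samples: treatments, moisture, b1..b6, 48 texture columns."""
    import pandas as pd

    rows = []
    for s in samples:
        row = {
            "plot_id": s.plot_id,
            "season": s.season,
            "mulch": s.mulch,
            "irrigation": s.irrigation,
            "moisture_pct": s.moisture_pct,
        }
        if s.reflectance is not None:
            row.update({f"b{i+1}": s.reflectance[i] for i in range(6)})
        if s.texture is not None:
            row.update(dict(zip(TEXTURE_FEATURE_NAMES, s.texture)))
        rows.append(row)
    return pd.DataFrame(rows)
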