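"""Gray-level co-occurrence texture features over plot regions.

For each band, a square window (default 7x7) slides over the region; inside
every window the gray-level co-occurrence matrix (GLCM) at a fixed spatial
offset (default displacement (1, 1), i.e. one pixel down and one right,
matching the common remote-sensing default shift of X=1, Y=1) is formed
from gray levels quantized to a fixed count (default 64) over the band's
scene-wide min-max range (per-region binning available, see
:class:`GlcmConfig`).  The GLCM is symmetric by default: each pixel pair
is counted in both directions.

Eight scalar measures summarise each window's normalized GLCM P(i, j):

    MEA = sum_i sum_j i * P(i, j)
    VAR = sum (i - MEA)^2 * P
    HOM = sum P / (1 + (i - j)^2)          (homogeneity / IDM)
    CON = sum (i - j)^2 * P                (contrast)
    DIS = sum |i - j| * P                  (dissimilarity)
    ENT = -sum P * ln P, with 0 ln 0 = 0   (entropy, natural log)
    SEM = sum P^2                          (second moment / energy)
    COR = sum (i - mu_i)(j - mu_j) P / (sigma_i sigma_j)

A region's feature value is the average of the window values over all
window centers whose full window (and hence every offset pair) lies inside
the region.  No padding is used, so no fabricated pixels enter the
statistics.  Windows with zero gray-level variance have an undefined COR;
those windows contribute 0-by-convention to nothing — they are excluded
from the regional COR average (and counted), while the other seven measures
still include them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .types import TEXTURE_FEATURE_NAMES, MultispectralScene, PlotRegion

__all__ = [
    "FEATURE_CODES",
    "GlcmConfig",
    "quantize",
    "cooccurrence",
    "texture_features",
    "glcm_feature_maps",
    "region_texture",
    "scene_texture_table",
]

#: Short codes for the eight measures, in output order.
FEATURE_CODES = ("MEA", "VAR", "HOM", "CON", "DIS", "ENT", "SEM", "COR")


@dataclass(frozen=True)
class GlcmConfig:
    """GLCM extraction parameters.

    ``quantization`` picks the gray-level binning range: ``"scene"``
    (default) bins each band over its full-raster min-max, so regions with
    larger spatial variability spread over more gray levels and amplitude
    differences between plots survive into the texture features;
    ``"region"`` bins each region over its own min-max, which normalises
    local contrast away (every region uses the full level range).  The two
    conventions give different feature values; which one a given vendor
    toolchain applies is often undocumented, hence the switch.
    """

    window: int = 7
    offset: tuple[int, int] = (1, 1)
    levels: int = 64
    symmetric: bool = True
    quantization: str = "scene"

    def __post_init__(self) -> None:
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError("window must be odd and >= 3")
        if self.levels < 2:
            raise ValueError("levels must be >= 2")
        dr, dc = self.offset
        if dr == 0 and dc == 0:
            raise ValueError("offset must be nonzero")
        if max(abs(dr), abs(dc)) >= self.window:
            raise ValueError("offset must be smaller than the window")
        if self.quantization not in ("scene", "region"):
            raise ValueError("quantization must be 'scene' or 'region'")


def quantize(values, levels: int, value_range: tuple[float, float] | None = None) -> np.ndarray:
    """Linear-bin values into ``levels`` integer gray levels.

    Bins partition ``value_range`` (default: [min, max] of the input);
    values outside the range clip to the end bins; a degenerate range maps
    everything to level 0.  Returns an integer array of the same shape.
    """
    if levels < 2:
        raise ValueError("levels must be >= 2")
    values = np.asarray(values, dtype=float)
    if value_range is None:
        lo, hi = values.min(), values.max()
    else:
        lo, hi = value_range
        if hi < lo:
            raise ValueError("value_range must be (low, high)")
    if hi == lo:
        return np.zeros(values.shape, dtype=np.int64)
    q = np.floor((values - lo) / (hi - lo) * levels).astype(np.int64)
    return np.clip(q, 0, levels - 1)


def _offset_pairs(arr: np.ndarray, offset: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Reference and neighbour gray levels for every in-bounds pair."""
    dr, dc = offset
    rows, cols = arr.shape
    if abs(dr) >= rows or abs(dc) >= cols:
        return np.empty(0, dtype=arr.dtype), np.empty(0, dtype=arr.dtype)
    ar = slice(0, rows - dr) if dr >= 0 else slice(-dr, rows)
    br = slice(dr, rows) if dr >= 0 else slice(0, rows + dr)
    ac = slice(0, cols - dc) if dc >= 0 else slice(-dc, cols)
    bc = slice(dc, cols) if dc >= 0 else slice(0, cols + dc)
    return arr[ar, ac].ravel(), arr[br, bc].ravel()


def cooccurrence(
    int_window,
    offset: tuple[int, int] = (1, 1),
    symmetric: bool = True,
    levels: int | None = None,
) -> np.ndarray:
    """Normalized co-occurrence matrix of an integer window.

    Parameters
    ----------
    int_window : 2-D integer array of gray levels >= 0.
    offset : (dr, dc) displacement between paired pixels.
    symmetric : count each pair in both directions (P becomes symmetric).
    levels : matrix side length; defaults to ``max(int_window) + 1``.

    Returns
    -------
    (levels, levels) float array summing to 1.
    """
    w = np.asarray(int_window)
    if w.ndim != 2:
        raise ValueError("window must be 2-D")
    if not np.issubdtype(w.dtype, np.integer):
        raise ValueError("window must be an integer array (quantize first)")
    if w.size and w.min() < 0:
        raise ValueError("gray levels must be >= 0")
    if levels is None:
        levels = int(w.max()) + 1 if w.size else 1
    elif w.size and w.max() >= levels:
        raise ValueError("gray level exceeds `levels`")
    a, b = _offset_pairs(w, offset)
    if a.size == 0:
        raise ValueError(f"window of shape {w.shape} has no valid pairs for offset {offset}")
    counts = np.bincount(a * levels + b, minlength=levels * levels).astype(float)
    P = counts.reshape(levels, levels)
    if symmetric:
        P = P + P.T
    return P / P.sum()


def _features_from_pairs(i: np.ndarray, j: np.ndarray, p: np.ndarray) -> tuple[np.ndarray, bool]:
    """Eight measures from the sparse GLCM cells (i, j, weight p).

    Returns (features[8] in FEATURE_CODES order, correlation_defined).
    """
    mu_i = float(np.dot(p, i))
    mu_j = float(np.dot(p, j))
    d = i - j
    var = float(np.dot(p, (i - mu_i) ** 2))
    hom = float(np.dot(p, 1.0 / (1.0 + d * d)))
    con = float(np.dot(p, (d * d).astype(float)))
    dis = float(np.dot(p, np.abs(d).astype(float)))
    ent = float(-np.dot(p, np.log(p)))
    sem = float(np.dot(p, p))
    var_j = float(np.dot(p, (j - mu_j) ** 2))
    denom = np.sqrt(var * var_j)
    if denom > 0:
        cor = float(np.dot(p, (i - mu_i) * (j - mu_j)) / denom)
        cor_defined = True
    else:
        cor = 0.0  # sentinel for zero-variance windows
        cor_defined = False
    return np.array([mu_i, var, hom, con, dis, ent, sem, cor]), cor_defined


def texture_features(P) -> dict:
    """The eight measures of a normalized co-occurrence matrix.

    Returns a dict keyed by :data:`FEATURE_CODES`.  COR is 0 (sentinel)
    when either marginal has zero variance.
    """
    P = np.asarray(P, dtype=float)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ValueError("P must be a square matrix")
    total = P.sum()
    if not np.isclose(total, 1.0, atol=1e-9):
        raise ValueError(f"P must be normalized (sums to {total})")
    ii, jj = np.nonzero(P)
    vals, _ = _features_from_pairs(ii.astype(float), jj.astype(float), P[ii, jj])
    return dict(zip(FEATURE_CODES, vals))


def _window_pair_features(q: np.ndarray, config: GlcmConfig) -> tuple[np.ndarray, bool]:
    """Features of one quantized window, via unique pair counting."""
    a, b = _offset_pairs(q, config.offset)
    if config.symmetric:
        a, b = np.concatenate([a, b]), np.concatenate([b, a])
    codes = a * config.levels + b
    uniq, counts = np.unique(codes, return_counts=True)
    p = counts / counts.sum()
    return _features_from_pairs(
        (uniq // config.levels).astype(float), (uniq % config.levels).astype(float), p
    )


def glcm_feature_maps(
    raster,
    config: GlcmConfig = GlcmConfig(),
    include: np.ndarray | None = None,
    value_range: tuple[float, float] | None = None,
):
    """Windowed texture maps over a 2-D raster.

    Gray levels are quantized over ``value_range`` when given, else over
    the included pixels' min-max.  A window center is valid when its full
    ``window x window`` neighbourhood lies inside the raster and contains
    only included pixels.

    Returns
    -------
    maps : (8, rows, cols) float array, NaN at invalid centers.
    valid : boolean (rows, cols) array of valid centers.
    cor_defined : boolean (rows, cols), True where COR was well defined.
    """
    arr = np.asarray(raster, dtype=float)
    if arr.ndim != 2:
        raise ValueError("raster must be 2-D")
    h = config.window // 2
    if min(arr.shape) < config.window:
        raise ValueError(f"raster {arr.shape} smaller than window {config.window}")
    if include is None:
        include = np.ones(arr.shape, dtype=bool)
    if not include.any():
        raise ValueError("no included pixels")
    q = np.zeros(arr.shape, dtype=np.int64)
    q[include] = quantize(arr[include], config.levels, value_range)

    full = ndimage.minimum_filter(include.astype(np.uint8), size=config.window, mode="constant")
    valid = full.astype(bool)
    valid[:h, :] = valid[-h:, :] = False
    valid[:, :h] = valid[:, -h:] = False

    maps = np.full((8,) + arr.shape, np.nan)
    cor_def = np.zeros(arr.shape, dtype=bool)
    for r, c in zip(*np.nonzero(valid)):
        sub = q[r - h : r + h + 1, c - h : c + h + 1]
        maps[:, r, c], cor_def[r, c] = _window_pair_features(sub, config)
    return maps, valid, cor_def


def region_texture(
    scene: MultispectralScene,
    region: PlotRegion,
    config: GlcmConfig = GlcmConfig(),
) -> np.ndarray:
    """The 48-vector of regional texture features for one plot.

    Per band, window feature maps are averaged over the region's valid
    window centers; COR is averaged over centers where it is defined.
    Ordered band-major: Mean1 .. Correlation1, ..., Mean6 .. Correlation6.
    """
    (r0, r1, c0, c1), inside = region.pixel_mask(scene.shape)
    if inside.shape[0] < config.window or inside.shape[1] < config.window:
        raise ValueError(
            f"region {region.plot_id} (season {region.season}) is smaller than the "
            f"{config.window}x{config.window} analysis window"
        )
    out = np.empty(scene.n_bands * 8)
    for b in range(scene.n_bands):
        patch = scene.bands[b, r0:r1, c0:c1].astype(float)
        if config.quantization == "scene":
            band = scene.bands[b]
            vrange = (float(band.min()), float(band.max()))
        else:
            vrange = None
        maps, valid, cor_def = glcm_feature_maps(
            patch, config, include=inside, value_range=vrange
        )
        if not valid.any():
            raise ValueError(
                f"region {region.plot_id} (season {region.season}) has no valid "
                f"window centers for band {b + 1}"
            )
        feats = np.array([np.nanmean(maps[k][valid]) for k in range(7)])
        defined = valid & cor_def
        cor = float(np.mean(maps[7][defined])) if defined.any() else 0.0
        out[b * 8 : b * 8 + 7] = feats
        out[b * 8 + 7] = cor
    return out


def scene_texture_table(scene: MultispectralScene, config: GlcmConfig = GlcmConfig()):
    """Texture features for every plot region in a scene.

    Returns a DataFrame with plot_id, season and the 48 feature columns
    (Table-style names: Mean1 .. Correlation6).
    """
    import pandas as pd

    rows = []
    for region in scene.plots:
        vec = region_texture(scene, region, config)
        row = {"plot_id": region.plot_id, "season": region.season}
        row.update(dict(zip(TEXTURE_FEATURE_NAMES, vec)))
        rows.append(row)
    return pd.DataFrame(rows)
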