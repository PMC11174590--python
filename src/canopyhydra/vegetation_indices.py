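"""Vegetation indices from six-band mean plot reflectance.

The band layout follows the multispectral camera: band 1 blue (450 nm),
band 2 green (555 nm), band 3 red (660 nm), band 4 red edge (720 nm),
band 5 red edge (750 nm), band 6 near infrared (840 nm).

Ten classic indices are provided.  Two of them are implemented "as
published" in the source workflow even where that differs from the
canonical literature form, with flags to switch:

* OSAVI here uses the green band in place of red by default
  (``osavi_canonical=True`` restores the red-band form).
* MSAVI defaults to the canonical closed form
  ``0.5 * (2N + 1 - sqrt((2N + 1)^2 - 8(N - R)))``; the typographically
  ambiguous published variant (leading ``2N - 1`` and a squared band
  difference under the root) is available via ``msavi_as_printed=True``.

RDVI is read as ``sqrt((N - R)/(N + R))``, i.e. the square root of the
normalized difference; a negative radicand raises.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "VI_NAMES",
    "SingularIndexError",
    "compute_vi",
    "compute_all_vis",
]

#: Index names in canonical output order.
VI_NAMES = ("SAVI", "EVI", "MSR", "OSAVI", "RDVI", "MSAVI", "ARVI", "GNDVI", "MTCI", "CI")

_B, _G, _R, _RE1, _RE2, _NIR = range(6)


class SingularIndexError(ValueError):
    """Raised when an index formula hits a zero denominator or invalid radicand."""


def _check_reflectance(r) -> np.ndarray:
    r = np.asarray(r, dtype=float).ravel()
    if r.size != 6:
        raise ValueError(f"expected a 6-band reflectance vector, got length {r.size}")
    if not np.isfinite(r).all():
        raise ValueError("reflectance vector contains non-finite values")
    if np.any(r < 0) or np.any(r > 1):
        raise ValueError("reflectance must lie in [0, 1]")
    return r


def _div(num: float, den: float, name: str) -> float:
    if den == 0.0:
        raise SingularIndexError(f"{name}: zero denominator")
    return num / den


def compute_vi(
    name: str,
    r,
    *,
    osavi_canonical: bool = False,
    msavi_as_printed: bool = False,
    red_edge_band: int = 4,
) -> float:
    """Compute one vegetation index from a 6-band reflectance vector.

    Parameters
    ----------
    name : str
        One of :data:`VI_NAMES` (case-insensitive).
    r : array-like, shape (6,)
        Mean reflectance for bands 1..6, each in [0, 1].
    osavi_canonical, msavi_as_printed : bool
        Formula-variant switches, see module docstring.
    red_edge_band : {4, 5}
        Which red-edge band supplies R_RE for MTCI and CI.
    """
    r = _check_reflectance(r)
    if red_edge_band not in (4, 5):
        raise ValueError("red_edge_band must be 4 or 5")
    b, g, red, nir = r[_B], r[_G], r[_R], r[_NIR]
    re = r[red_edge_band - 1]
    key = name.upper()

    if key == "SAVI":
        return (1 + 0.5) * _div(nir - red, nir + red + 0.5, key)
    if key == "EVI":
        return 2.5 * _div(nir - red, nir + 6 * red - 7.5 * b + 1, key)
    if key == "MSR":
        sr = _div(nir, red, key)
        return (sr - 1) / np.sqrt(sr + 1)
    if key == "OSAVI":
        band = red if osavi_canonical else g
        return (1 + 0.16) * _div(nir - band, nir + band + 0.16, key)
    if key == "RDVI":
        q = _div(nir - red, nir + red, key)
        if q < 0:
            raise SingularIndexError("RDVI: negative radicand (R_NIR < R_RED)")
        return float(np.sqrt(q))
    if key == "MSAVI":
        if msavi_as_printed:
            rad = (2 * nir + 1) ** 2 - 8 * (nir - red) ** 2
            if rad < 0:
                raise SingularIndexError("MSAVI: negative radicand")
            return 0.5 * ((2 * nir - 1) + np.sqrt(rad))
        rad = (2 * nir + 1) ** 2 - 8 * (nir - red)
        if rad < 0:
            raise SingularIndexError("MSAVI: negative radicand")
        return 0.5 * (2 * nir + 1 - np.sqrt(rad))
    if key == "ARVI":
        return _div(nir - 2 * red + b, nir + 2 * red - b, key)
    if key == "GNDVI":
        return _div(nir - g, nir + g, key)
    if key == "MTCI":
        return _div(nir - re, re - red, key)
    if key == "CI":
        return _div(nir, re, key) - 1
    raise KeyError(f"unknown vegetation index {name!r}; known: {', '.join(VI_NAMES)}")


def compute_all_vis(
    samples,
    *,
    osavi_canonical: bool = False,
    msavi_as_printed: bool = False,
    red_edge_band: int = 4,
) -> pd.DataFrame:
    """Compute all ten indices for a table of samples.

    Parameters
    ----------
    samples : DataFrame with columns b1..b6, or iterable of objects with a
        ``reflectance`` attribute (6-vector), or an (n, 6) array.

    Returns
    -------
    DataFrame with one row per sample and the ten index columns in
    :data:`VI_NAMES` order.  The input row index is preserved for
    DataFrames.
    """
    if isinstance(samples, pd.DataFrame):
        cols = [f"b{i}" for i in range(1, 7)]
        missing = [c for c in cols if c not in samples.columns]
        if missing:
            raise ValueError(f"missing reflectance columns: {missing}")
        mat = samples[cols].to_numpy(dtype=float)
        index = samples.index
    elif isinstance(samples, np.ndarray):
        mat = np.atleast_2d(np.asarray(samples, dtype=float))
        index = None
    else:
        rows = list(samples)
        mat = np.array([np.asarray(getattr(s, "reflectance", s), dtype=float) for s in rows])
        index = None
    out = pd.DataFrame(
        [
            {
                n: compute_vi(
                    n,
                    row,
                    osavi_canonical=osavi_canonical,
                    msavi_as_printed=msavi_as_printed,
                    red_edge_band=red_edge_band,
                )
                for n in VI_NAMES
            }
            for row in mat
        ],
        columns=list(VI_NAMES),
    )
    if index is not None:
        out.index = index
    return out
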