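"""Exhaustive two-feature texture-index search against leaf moisture.

Six index families combine a pair of texture features (Ti, Tj):

    RTI  = Ti / Tj                ratio texture index
    DTI  = Ti - Tj                difference texture index
    ATI  = Ti + Tj                additive texture index
    NDTI = (Ti - Tj) / (Ti + Tj)  normalized difference texture index
    RDTI = 1/Ti - 1/Tj            reciprocal difference texture index
    RATI = 1/Ti + 1/Tj            reciprocal additive texture index

For each family, every ordered pair (i, j), i != j, of the 48 regional
texture features is turned into an index vector across samples and
correlated (Pearson) with moisture; the pair maximizing |r| is reported
together with the full 48 x 48 correlation matrix (the heat-map analog).
Because the best pair is selected post hoc over ~2.2k candidates, the
naive p-value of the winner is optimistic; an optional seeded permutation
test provides a selection-adjusted p for the family-wise maximum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FAMILY_NAMES",
    "TextureIndexHit",
    "texture_index",
    "pairwise_index_stack",
    "search_family",
    "search_all",
    "permutation_pvalue",
]

FAMILY_NAMES = ("RTI", "DTI", "ATI", "NDTI", "RDTI", "RATI")


class SingularPairError(ValueError):
    """An index formula is undefined at one or more samples."""


@dataclass(frozen=True)
class TextureIndexHit:
    """Best feature pair of one family."""

    family: str
    feature_i: str
    feature_j: str
    r: float
    p: float
    n: int
    n_singular_pairs: int = 0
    p_permutation: float | None = None


def _apply_family(family: str, ti: np.ndarray, tj: np.ndarray) -> np.ndarray:
    if family == "RTI":
        return ti / tj
    if family == "DTI":
        return ti - tj
    if family == "ATI":
        return ti + tj
    if family == "NDTI":
        return (ti - tj) / (ti + tj)
    if family == "RDTI":
        return 1.0 / ti - 1.0 / tj
    if family == "RATI":
        return 1.0 / ti + 1.0 / tj
    raise KeyError(f"unknown texture-index family {family!r}; known: {FAMILY_NAMES}")


def texture_index(family: str, Ti, Tj) -> np.ndarray:
    """Elementwise texture index of one family for two feature vectors."""
    ti = np.asarray(Ti, dtype=float)
    tj = np.asarray(Tj, dtype=float)
    if ti.shape != tj.shape:
        raise ValueError("Ti and Tj must have the same shape")
    family = family.upper()
    if family in ("RTI", "NDTI", "RDTI", "RATI"):
        if family == "NDTI":
            bad = np.nonzero(ti + tj == 0)[0]
        elif family == "RTI":
            bad = np.nonzero(tj == 0)[0]
        else:
            bad = np.nonzero((ti == 0) | (tj == 0))[0]
        if bad.size:
            raise SingularPairError(
                f"{family}: singular denominator at sample index {bad[0]}"
            )
    return _apply_family(family, ti, tj)


def _pearson_matrix(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson r of each column of X (n, m) with y (n,); NaN where undefined."""
    y = y - y.mean()
    sy = np.sqrt((y**2).sum())
    Xc = X - X.mean(axis=0)
    sx = np.sqrt((Xc**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc * y[:, None]).sum(axis=0) / (sx * sy)
    r[sx == 0] = np.nan
    return r


def _pvalue_from_r(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p from the t statistic r*sqrt((n-2)/(1-r^2)) on n-2 df."""
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    return np.where(np.isnan(r), np.nan, p)


def pairwise_index_stack(family: str, T: np.ndarray) -> np.ndarray:
    """Index vectors for all ordered pairs: (n, m, m) array, [s, i, j].

    Singular cells (any sample hitting a zero denominator) are NaN across
    all samples; the diagonal is NaN (RTI would be identically 1, NDTI
    identically 0 — degenerate).
    """
    family = family.upper()
    n, m = T.shape
    ti = T[:, :, None]
    tj = T[:, None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        idx = _apply_family(family, ti, tj)
    if family == "NDTI":
        singular = (ti + tj == 0).any(axis=0)
    elif family == "RTI":
        singular = np.broadcast_to((T == 0).any(axis=0)[None, :], (m, m)).copy()
    elif family in ("RDTI", "RATI"):
        zero = (T == 0).any(axis=0)
        singular = zero[:, None] | zero[None, :]
    else:
        singular = np.zeros((m, m), dtype=bool)
    idx[:, singular] = np.nan
    idx[:, np.arange(m), np.arange(m)] = np.nan
    return idx


def search_family(
    family: str,
    texture_table: pd.DataFrame,
    moisture,
    *,
    n_permutations: int = 0,
    seed: int | None = None,
) -> tuple[TextureIndexHit, pd.DataFrame]:
    """Find the feature pair of one family most correlated with moisture.

    Parameters
    ----------
    texture_table : DataFrame
        Samples x texture-feature columns (typically 48).
    moisture : array-like, length n
        Leaf moisture content per sample (%).
    n_permutations : int
        If > 0, also compute a permutation-adjusted p-value for the
        family-wise maximum |r| with this many seeded permutations.

    Returns
    -------
    (hit, matrix) : the best :class:`TextureIndexHit` (max |r|, ties broken
    by first occurrence in column order) and the full correlation matrix
    as a DataFrame (rows = Ti, cols = Tj; NaN on the diagonal and at
    singular pairs).
    """
    family = family.upper()
    y = np.asarray(moisture, dtype=float)
    T = texture_table.to_numpy(dtype=float)
    n, m = T.shape
    if y.shape != (n,):
        raise ValueError("moisture length must match the table's row count")
    if n < 3:
        raise ValueError("need at least 3 samples")
    if np.isnan(T).any() or np.isnan(y).any():
        raise ValueError("missing values in inputs")

    idx = pairwise_index_stack(family, T)
    flat = idx.reshape(n, m * m)
    computable = ~np.isnan(flat).any(axis=0)
    r_flat = np.full(m * m, np.nan)
    if computable.any():
        r_flat[computable] = _pearson_matrix(flat[:, computable], y)
    if np.isnan(r_flat).all():
        raise SingularPairError(f"{family}: every feature pair is singular or constant")

    # first index of the max |r| in row-major (band-major) order
    absr = np.abs(r_flat)
    best_flat = int(np.nanargmax(absr))
    bi, bj = divmod(best_flat, m)
    r_best = float(r_flat[best_flat])
    p_best = float(_pvalue_from_r(np.array([r_best]), n)[0])
    n_singular = int(m * m - m - computable.sum())

    p_perm = None
    if n_permutations > 0:
        p_perm = permutation_pvalue(
            flat[:, computable], y, abs(r_best), n_permutations, seed
        )

    cols = list(texture_table.columns)
    hit = TextureIndexHit(
        family=family,
        feature_i=cols[bi],
        feature_j=cols[bj],
        r=r_best,
        p=p_best,
        n=n,
        n_singular_pairs=n_singular,
        p_permutation=p_perm,
    )
    matrix = pd.DataFrame(r_flat.reshape(m, m), index=cols, columns=cols)
    return hit, matrix


def permutation_pvalue(
    X: np.ndarray, y: np.ndarray, observed_max_abs_r: float, n_permutations: int, seed
) -> float:
    """Selection-adjusted p for a family-wise max |r| via moisture permutation."""
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        perm = rng.permutation(y)
        r = _pearson_matrix(X, perm)
        if np.nanmax(np.abs(r)) >= observed_max_abs_r:
            exceed += 1
    return (1 + exceed) / (n_permutations + 1)


def search_all(
    texture_table: pd.DataFrame,
    moisture,
    *,
    n_permutations: int = 0,
    seed: int | None = None,
) -> tuple[dict[str, TextureIndexHit], dict[str, pd.DataFrame]]:
    """Run :func:`search_family` for all six families."""
    hits: dict[str, TextureIndexHit] = {}
    matrices: dict[str, pd.DataFrame] = {}
    for fam in FAMILY_NAMES:
        hit, mat = search_family(
            fam, texture_table, moisture, n_permutations=n_permutations, seed=seed
        )
        hits[fam] = hit
        matrices[fam] = mat
    return hits, matrices


def best_index_columns(
    hits: dict[str, TextureIndexHit], texture_table: pd.DataFrame
) -> pd.DataFrame:
    """Materialize each family's best index as a sample-vector column.

    Columns are named by family (the combination-3 convention), with the
    winning pair recorded in ``DataFrame.attrs['pairs']``.
    """
    out = {}
    pairs = {}
    for fam, hit in hits.items():
        out[fam] = texture_index(
            fam, texture_table[hit.feature_i], texture_table[hit.feature_j]
        )
    df = pd.DataFrame(out, index=texture_table.index)
    df.attrs["pairs"] = {f: (h.feature_i, h.feature_j) for f, h in hits.items()}
    return df
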