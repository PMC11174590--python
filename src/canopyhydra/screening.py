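"""Correlation screening and assembly of model input combinations.

Every candidate feature (vegetation index, texture feature, or best
texture-index column) is correlated with leaf moisture; features whose
two-sided Pearson p-value falls below alpha (default 0.05) are retained.
No multiple-testing correction is applied by default, matching the common
practice in this workflow; a Benjamini-Hochberg option is available.

Four input combinations are assembled for the model stage:

1. significant vegetation indices,
2. significant texture features,
3. the per-family best texture-index columns (significant ones),
4. the union of 1-3 in that order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CorrelationRecord",
    "FeatureCombination",
    "pearson_with_p",
    "screen",
    "build_combinations",
]

COMBINATION_NAMES = ("combination1", "combination2", "combination3", "combination4")


@dataclass(frozen=True)
class CorrelationRecord:
    feature_name: str
    r: float
    p: float
    n: int
    significant: bool


@dataclass(frozen=True)
class FeatureCombination:
    """A named, ordered set of feature columns."""

    name: str
    columns: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.columns)) != len(self.columns):
            raise ValueError(f"{self.name}: duplicate columns")

    def __len__(self) -> int:
        return len(self.columns)


def pearson_with_p(x, y) -> tuple[float, float]:
    """Pearson r and two-sided p-value.

    The p-value is the exact two-sided tail of the t statistic
    ``r * sqrt((n - 2) / (1 - r^2))`` on ``n - 2`` degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 samples")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance input")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def _vectorized_screen(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = X.shape[0]
    yc = y - y.mean()
    sy = np.sqrt((yc**2).sum())
    Xc = X - X.mean(axis=0)
    sx = np.sqrt((Xc**2).sum(axis=0))
    if sy == 0:
        raise ValueError("moisture has zero variance")
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc * yc[:, None]).sum(axis=0) / (sx * sy)
    # constant features have no defined correlation; they are reported as
    # NaN and can never be significant
    r = np.where(sx == 0, np.nan, np.clip(r, -1.0, 1.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = np.where(np.abs(r) >= 1.0, 0.0, 2.0 * stats.t.sf(np.abs(t), df=n - 2))
    return r, np.where(np.isnan(r), np.nan, p)


def screen(
    features_table: pd.DataFrame,
    moisture,
    alpha: float = 0.05,
    *,
    bh_correction: bool = False,
) -> list[CorrelationRecord]:
    """Correlate every column with moisture and flag significance.

    Returns one :class:`CorrelationRecord` per column, in column order.
    With ``bh_correction=True`` the significance flag uses
    Benjamini-Hochberg-adjusted p-values (the reported ``p`` stays raw).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    y = np.asarray(moisture, dtype=float)
    X = features_table.to_numpy(dtype=float)
    if X.shape[0] != y.size:
        raise ValueError("moisture length must match the table's row count")
    if X.shape[0] < 3:
        raise ValueError("need at least 3 samples")
    r, p = _vectorized_screen(X, y)
    if bh_correction:
        from statsmodels.stats.multitest import multipletests

        sig = multipletests(p, alpha=alpha, method="fdr_bh")[0]
    else:
        sig = p < alpha
    n = X.shape[0]
    return [
        CorrelationRecord(c, float(r[k]), float(p[k]), n, bool(sig[k]))
        for k, c in enumerate(features_table.columns)
    ]


def records_frame(records: list[CorrelationRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"feature": rec.feature_name, "r": rec.r, "p": rec.p, "n": rec.n,
             "significant": rec.significant}
            for rec in records
        ]
    )


def build_combinations(
    vi_records: list[CorrelationRecord],
    tex_records: list[CorrelationRecord],
    ti_records: list[CorrelationRecord],
) -> dict[str, FeatureCombination]:
    """Assemble the four model-input combinations from screening output.

    Each combination keeps only the significant members of its source
    family, in their screened order; combination 4 is the ordered union
    (vegetation indices, then texture features, then texture indices).
    An empty combination is returned as such — the model stage refuses it.
    """
    def sig(records):
        return tuple(r.feature_name for r in records if r.significant)

    c1, c2, c3 = sig(vi_records), sig(tex_records), sig(ti_records)
    combos = {
        "combination1": FeatureCombination("combination1", c1),
        "combination2": FeatureCombination("combination2", c2),
        "combination3": FeatureCombination("combination3", c3),
        "combination4": FeatureCombination("combination4", c1 + c2 + c3),
    }
    for combo in combos.values():
        if len(combo) == 0:
            import warnings

            warnings.warn(
                f"{combo.name} has no significant features; models will refuse it",
                stacklevel=2,
            )
    return combos
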