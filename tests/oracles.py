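"""Independent brute-force oracles used by the unit and acceptance tests.

Everything here is deliberately naive (explicit Python loops, dense
matrices, scipy per-pair calls) and shares no code path with the package
implementation it checks.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats


def naive_cooccurrence(window: np.ndarray, offset: tuple[int, int], symmetric: bool,
                       levels: int) -> np.ndarray:
    """Pair-enumeration GLCM: explicit double loop over pixels."""
    dr, dc = offset
    rows, cols = window.shape
    P = np.zeros((levels, levels), dtype=float)
    for r in range(rows):
        for c in range(cols):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < rows and 0 <= c2 < cols:
                P[window[r, c], window[r2, c2]] += 1
                if symmetric:
                    P[window[r2, c2], window[r, c]] += 1
    total = P.sum()
    return P / total


def naive_features(P: np.ndarray) -> dict:
    """The eight co-occurrence measures via dense double loops."""
    n = P.shape[0]
    mu_i = sum(i * P[i, j] for i in range(n) for j in range(n))
    mu_j = sum(j * P[i, j] for i in range(n) for j in range(n))
    var_i = sum((i - mu_i) ** 2 * P[i, j] for i in range(n) for j in range(n))
    var_j = sum((j - mu_j) ** 2 * P[i, j] for i in range(n) for j in range(n))
    hom = sum(P[i, j] / (1 + (i - j) ** 2) for i in range(n) for j in range(n))
    con = sum((i - j) ** 2 * P[i, j] for i in range(n) for j in range(n))
    dis = sum(abs(i - j) * P[i, j] for i in range(n) for j in range(n))
    ent = -sum(
        P[i, j] * math.log(P[i, j])
        for i in range(n)
        for j in range(n)
        if P[i, j] > 0
    )
    sem = sum(P[i, j] ** 2 for i in range(n) for j in range(n))
    denom = math.sqrt(var_i * var_j)
    if denom > 0:
        cor = sum(
            (i - mu_i) * (j - mu_j) * P[i, j] for i in range(n) for j in range(n)
        ) / denom
    else:
        cor = 0.0
    return {
        "MEA": mu_i, "VAR": var_i, "HOM": hom, "CON": con,
        "DIS": dis, "ENT": ent, "SEM": sem, "COR": cor,
    }


def apply_index(family: str, ti, tj):
    ti = np.asarray(ti, dtype=float)
    tj = np.asarray(tj, dtype=float)
    return {
        "RTI": ti / tj,
        "DTI": ti - tj,
        "ATI": ti + tj,
        "NDTI": (ti - tj) / (ti + tj),
        "RDTI": 1 / ti - 1 / tj,
        "RATI": 1 / ti + 1 / tj,
    }[family]


def brute_force_search(family: str, table, moisture):
    """Double-loop exhaustive pair search with scipy pearsonr.

    Returns (best_i_name, best_j_name, best_r, r_matrix) with ties broken
    by first occurrence in (row-major) column order; singular or constant
    pairs are skipped and NaN in the matrix.
    """
    cols = list(table.columns)
    m = len(cols)
    y = np.asarray(moisture, dtype=float)
    best = None
    R = np.full((m, m), np.nan)
    for a in range(m):
        for b in range(m):
            if a == b:
                continue
            ti = table[cols[a]].to_numpy(dtype=float)
            tj = table[cols[b]].to_numpy(dtype=float)
            if family in ("RTI",) and np.any(tj == 0):
                continue
            if family in ("RDTI", "RATI") and (np.any(ti == 0) or np.any(tj == 0)):
                continue
            if family == "NDTI" and np.any(ti + tj == 0):
                continue
            vec = apply_index(family, ti, tj)
            if np.std(vec) == 0:
                continue
            r = stats.pearsonr(vec, y).statistic
            R[a, b] = r
            if best is None or abs(r) > abs(best[2]) + 1e-15:
                best = (cols[a], cols[b], r)
    return best[0], best[1], best[2], R
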