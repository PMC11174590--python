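"""Evaluation metrics for moisture-retrieval models.

Leaf moisture content (LMC) is expressed as the water fraction of leaf fresh
mass, in percent:

    LMC = 100 * (m_fresh - m_dry) / m_fresh

Model fits are scored by the coefficient of determination (R^2), the root
mean square error (RMSE, same units as moisture, i.e. percentage points),
and the mean relative error (MRE, percent).

Two R^2 conventions exist in the agronomic remote-sensing literature: the
residual form 1 - SS_res/SS_tot and the explained-variance form
SS_reg/SS_tot.  They coincide for an OLS fit evaluated on its own training
data but diverge for arbitrary predictions; the residual form is the default
because validation-set R^2 is conventionally reported that way.
"""

from __future__ import annotations

import numpy as np

__all__ = ["leaf_moisture_pct", "r2", "rmse", "mre"]


def _as_float_arrays(obs, pred) -> tuple[np.ndarray, np.ndarray]:
    obs = np.asarray(obs, dtype=float).ravel()
    pred = np.asarray(pred, dtype=float).ravel()
    if obs.shape != pred.shape:
        raise ValueError(
            f"obs and pred have mismatched lengths {obs.size} vs {pred.size}"
        )
    if obs.size == 0:
        raise ValueError("empty input")
    if not (np.isfinite(obs).all() and np.isfinite(pred).all()):
        raise ValueError("non-finite values in obs or pred")
    return obs, pred


def leaf_moisture_pct(fresh_mass, dry_mass):
    """Leaf moisture content in percent of fresh mass.

    Parameters
    ----------
    fresh_mass, dry_mass : float or array-like
        Fresh and oven-dry mass of the same leaf sample, any common unit.

    Returns
    -------
    float or ndarray
        ``100 * (fresh - dry) / fresh``, in (0, 100].
    """
    fresh = np.asarray(fresh_mass, dtype=float)
    dry = np.asarray(dry_mass, dtype=float)
    if np.any(fresh <= 0):
        raise ValueError("fresh mass must be positive")
    if np.any(dry <= 0):
        raise ValueError("dry mass must be positive")
    if np.any(dry > fresh):
        raise ValueError("dry mass exceeds fresh mass")
    out = 100.0 * (fresh - dry) / fresh
    return float(out) if out.ndim == 0 else out


def r2(obs, pred, *, explained_variance: bool = False) -> float:
    """Coefficient of determination.

    By default the residual form ``1 - SS_res/SS_tot``.  With
    ``explained_variance=True`` the form ``sum((pred - mean(obs))^2) /
    sum((obs - mean(obs))^2)`` is used instead; the two agree for
    least-squares-consistent predictions on the training set.
    """
    obs, pred = _as_float_arrays(obs, pred)
    ybar = obs.mean()
    ss_tot = np.sum((obs - ybar) ** 2)
    if ss_tot == 0.0:
        raise ValueError("observations have zero variance; R^2 undefined")
    if explained_variance:
        return float(np.sum((pred - ybar) ** 2) / ss_tot)
    return float(1.0 - np.sum((obs - pred) ** 2) / ss_tot)


def rmse(obs, pred) -> float:
    """Root mean square error, in the units of the observations."""
    obs, pred = _as_float_arrays(obs, pred)
    return float(np.sqrt(np.mean((pred - obs) ** 2)))


def mre(obs, pred) -> float:
    """Mean absolute relative error, in percent.

    Relative errors are taken in absolute value; signed relative errors
    would cancel and report a near-zero error for any unbiased model.
    """
    obs, pred = _as_float_arrays(obs, pred)
    if np.any(obs <= 0):
        raise ValueError("observations must be strictly positive for MRE")
    return float(np.mean(np.abs(pred - obs) / obs) * 100.0)
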