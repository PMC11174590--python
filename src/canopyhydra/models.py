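"""Regression models for moisture retrieval, as scikit-learn estimators.

Three regressors are compared on each feature combination:

* :class:`ELMRegressor` — extreme learning machine: a single hidden layer
  of sigmoid units with *fixed* random weights drawn uniform in [-1, 1];
  only the output weights are fitted, by least squares via the
  pseudoinverse.  Over a number of seeded restarts the draw with the best
  training RMSE is kept (validation data are never consulted).
* XGBoost — gradient-boosted regression trees via :mod:`xgboost`, with
  100 estimators, learning rate 0.03, depth 5.
* :class:`LMBackpropRegressor` — a one-hidden-layer tanh network with
  linear output trained by Levenberg-Marquardt on the sum-of-squares
  loss: each step solves (J'J + mu I) d = J'e with mu adapted (x10 on a
  rejected step, /10 on an accepted one).

Inputs are z-scored with training-set statistics before the two neural
models (bounded activations need comparable scales); the tree model sees
raw features.  The target is also z-scored inside the LM network and
unscaled at prediction time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted, validate_data

from . import metrics as _metrics
from .screening import FeatureCombination

__all__ = [
    "SplitSpec",
    "ElmSpec",
    "XgbSpec",
    "BpnnSpec",
    "FitReport",
    "ELMRegressor",
    "LMBackpropRegressor",
    "split",
    "fit_elm",
    "fit_xgb",
    "fit_bpnn",
    "evaluate",
    "run_matrix",
]


# --------------------------------------------------------------------------
# specs and split

@dataclass(frozen=True)
class SplitSpec:
    """Random train/validation partition (no stratification)."""

    train_fraction: float = 2.0 / 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must lie in (0, 1)")


def split(n_samples: int, spec: SplitSpec = SplitSpec()) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint (train_idx, val_idx) covering range(n_samples).

    |train| = round(train_fraction * n); deterministic per seed.
    """
    if n_samples < 2:
        raise ValueError("need at least 2 samples to split")
    rng = np.random.default_rng(spec.seed)
    perm = rng.permutation(n_samples)
    n_train = int(round(spec.train_fraction * n_samples))
    n_train = min(max(n_train, 1), n_samples - 1)
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])


@dataclass(frozen=True)
class ElmSpec:
    hidden_neurons: int = 60
    weight_range: tuple[float, float] = (-1.0, 1.0)
    restarts: int = 50
    seed: int = 0


@dataclass(frozen=True)
class XgbSpec:
    n_estimators: int = 100
    learning_rate: float = 0.03
    max_depth: int = 5
    seed: int = 0


@dataclass(frozen=True)
class BpnnSpec:
    hidden_neurons: int = 15
    max_epochs: int = 1000
    tol: float = 1e-8
    patience: int = 10
    seed: int = 0


@dataclass
class FitReport:
    model: str
    combination: str
    train_pred: np.ndarray
    val_pred: np.ndarray
    metrics_train: dict
    metrics_val: dict


# --------------------------------------------------------------------------
# estimators

def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


class ELMRegressor(RegressorMixin, BaseEstimator):
    """Extreme learning machine regressor.

    Hidden layer H = sigmoid(X W + b) with W, b drawn uniform in
    ``weight_range``; output weights are the minimum-norm least-squares
    solution ``pinv(H) @ y``.  ``restarts`` independent draws are made and
    the one with the lowest *training* RMSE is kept.

    Parameters
    ----------
    hidden_neurons : int, default 60
    weight_range : (low, high), default (-1, 1)
    restarts : int, default 50
    standardize : bool, default True
        z-score features with training statistics before the hidden layer.
    random_state : int or None

    Attributes
    ----------
    hidden_weights_, hidden_biases_ : the winning random projection.
    output_weights_ : fitted least-squares output layer.
    train_rmse_ : training RMSE of the winning restart.
    """

    def __init__(
        self,
        hidden_neurons: int = 60,
        weight_range: tuple[float, float] = (-1.0, 1.0),
        restarts: int = 50,
        standardize: bool = True,
        random_state: Optional[int] = None,
    ):
        self.hidden_neurons = hidden_neurons
        self.weight_range = weight_range
        self.restarts = restarts
        self.standardize = standardize
        self.random_state = random_state

    def _standardize(self, X: np.ndarray) -> np.ndarray:
        return (X - self.x_mean_) / self.x_scale_

    def fit(self, X, y):
        X, y = validate_data(self, X, y, y_numeric=True)
        if self.hidden_neurons < 1:
            raise ValueError("hidden_neurons must be >= 1")
        if self.restarts < 1:
            raise ValueError("restarts must be >= 1")
        lo, hi = self.weight_range
        if not lo < hi:
            raise ValueError("weight_range must be (low, high) with low < high")
        if self.standardize:
            self.x_mean_ = X.mean(axis=0)
            scale = X.std(axis=0)
            self.x_scale_ = np.where(scale == 0, 1.0, scale)
        else:
            self.x_mean_ = np.zeros(X.shape[1])
            self.x_scale_ = np.ones(X.shape[1])
        Xs = self._standardize(X)
        rng = np.random.default_rng(self.random_state)
        best = None
        for _ in range(self.restarts):
            W = rng.uniform(lo, hi, size=(X.shape[1], self.hidden_neurons))
            b = rng.uniform(lo, hi, size=self.hidden_neurons)
            H = _sigmoid(Xs @ W + b)
            beta = np.linalg.pinv(H) @ y
            rmse = float(np.sqrt(np.mean((H @ beta - y) ** 2)))
            if best is None or rmse < best[0]:
                best = (rmse, W, b, beta)
        self.train_rmse_, self.hidden_weights_, self.hidden_biases_, self.output_weights_ = best
        return self

    def predict(self, X):
        check_is_fitted(self)
        X = validate_data(self, X, reset=False)
        H = _sigmoid(self._standardize(X) @ self.hidden_weights_ + self.hidden_biases_)
        return H @ self.output_weights_


class LMBackpropRegressor(RegressorMixin, BaseEstimator):
    """One-hidden-layer tanh network trained by Levenberg-Marquardt.

    Architecture: ``yhat = tanh(X W1 + b1) @ w2 + b2`` with
    ``hidden_neurons`` tanh units and a linear output.  Training minimises
    the sum of squared residuals with the damped Gauss-Newton update
    ``d = (J'J + mu I)^(-1) J'e``; mu is multiplied by 10 when a step is
    rejected (SSE would increase) and divided by 10 when accepted.
    Training stops when the SSE improvement stays below ``tol`` for
    ``patience`` accepted epochs, when mu exceeds ``mu_max``, or at
    ``max_epochs``.

    Attributes
    ----------
    sse_path_ : ndarray of accepted-epoch SSE values (non-increasing).
    n_epochs_ : number of accepted epochs run.
    """

    def __init__(
        self,
        hidden_neurons: int = 15,
        max_epochs: int = 1000,
        tol: float = 1e-8,
        patience: int = 10,
        mu_init: float = 1e-3,
        mu_factor: float = 10.0,
        mu_max: float = 1e10,
        standardize: bool = True,
        random_state: Optional[int] = None,
    ):
        self.hidden_neurons = hidden_neurons
        self.max_epochs = max_epochs
        self.tol = tol
        self.patience = patience
        self.mu_init = mu_init
        self.mu_factor = mu_factor
        self.mu_max = mu_max
        self.standardize = standardize
        self.random_state = random_state

    def _scale_x(self, X: np.ndarray) -> np.ndarray:
        return (X - self.x_mean_) / self.x_scale_

    @staticmethod
    def _unpack(theta: np.ndarray, d: int, h: int):
        W1 = theta[: d * h].reshape(d, h)
        b1 = theta[d * h : d * h + h]
        w2 = theta[d * h + h : d * h + 2 * h]
        b2 = theta[-1]
        return W1, b1, w2, b2

    def _forward(self, Xs: np.ndarray, theta: np.ndarray):
        W1, b1, w2, b2 = self._unpack(theta, Xs.shape[1], self.hidden_neurons)
        A = np.tanh(Xs @ W1 + b1)
        return A, A @ w2 + b2

    def fit(self, X, y):
        X, y = validate_data(self, X, y, y_numeric=True)
        if self.hidden_neurons < 1:
            raise ValueError("hidden_neurons must be >= 1")
        n, d = X.shape
        h = self.hidden_neurons
        if self.standardize:
            self.x_mean_, xsd = X.mean(axis=0), X.std(axis=0)
            self.x_scale_ = np.where(xsd == 0, 1.0, xsd)
            self.y_mean_, ysd = y.mean(), y.std()
            self.y_scale_ = ysd if ysd > 0 else 1.0
        else:
            self.x_mean_, self.x_scale_ = np.zeros(d), np.ones(d)
            self.y_mean_, self.y_scale_ = 0.0, 1.0
        Xs = self._scale_x(X)
        ys = (y - self.y_mean_) / self.y_scale_

        rng = np.random.default_rng(self.random_state)
        n_params = d * h + 2 * h + 1
        theta = rng.uniform(-0.5, 0.5, size=n_params)
        theta[: d * h] /= max(np.sqrt(d), 1.0)

        A, yhat = self._forward(Xs, theta)
        e = ys - yhat
        sse = float(e @ e)
        mu = self.mu_init
        path = [sse]
        stall = 0
        for _ in range(self.max_epochs):
            W1, b1, w2, b2 = self._unpack(theta, d, h)
            dA = 1.0 - A**2  # (n, h)
            # J columns: [W1 (d*h), b1 (h), w2 (h), b2 (1)]
            J = np.empty((n, n_params))
            J[:, : d * h] = (Xs[:, :, None] * (dA * w2)[:, None, :]).reshape(n, d * h)
            J[:, d * h : d * h + h] = dA * w2
            J[:, d * h + h : d * h + 2 * h] = A
            J[:, -1] = 1.0
            g = J.T @ e
            JtJ = J.T @ J
            accepted = False
            while mu <= self.mu_max:
                try:
                    step = np.linalg.solve(JtJ + mu * np.eye(n_params), g)
                except np.linalg.LinAlgError:
                    mu *= self.mu_factor
                    continue
                theta_new = theta + step
                A_new, yhat_new = self._forward(Xs, theta_new)
                e_new = ys - yhat_new
                sse_new = float(e_new @ e_new)
                if np.isfinite(sse_new) and sse_new < sse:
                    improvement = sse - sse_new
                    theta, A, e, sse = theta_new, A_new, e_new, sse_new
                    mu = max(mu / self.mu_factor, 1e-20)
                    path.append(sse)
                    accepted = True
                    stall = stall + 1 if improvement < self.tol else 0
                    break
                mu *= self.mu_factor
            if not accepted or stall >= self.patience:
                break
        self.theta_ = theta
        self.sse_path_ = np.asarray(path)
        self.n_epochs_ = len(path) - 1
        self.train_sse_ = sse
        return self

    def predict(self, X):
        check_is_fitted(self)
        X = validate_data(self, X, reset=False)
        _, yhat = self._forward(self._scale_x(X), self.theta_)
        return yhat * self.y_scale_ + self.y_mean_


# --------------------------------------------------------------------------
# thin functional wrappers and the model-by-combination grid

def fit_elm(train_X, train_y, spec: ElmSpec = ElmSpec()) -> ELMRegressor:
    est = ELMRegressor(
        hidden_neurons=spec.hidden_neurons,
        weight_range=spec.weight_range,
        restarts=spec.restarts,
        random_state=spec.seed,
    )
    return est.fit(train_X, train_y)


def fit_xgb(train_X, train_y, spec: XgbSpec = XgbSpec()):
    from xgboost import XGBRegressor

    est = XGBRegressor(
        n_estimators=spec.n_estimators,
        learning_rate=spec.learning_rate,
        max_depth=spec.max_depth,
        random_state=spec.seed,
        n_jobs=1,
    )
    return est.fit(np.asarray(train_X, dtype=float), np.asarray(train_y, dtype=float))


def fit_bpnn(train_X, train_y, spec: BpnnSpec = BpnnSpec()) -> LMBackpropRegressor:
    est = LMBackpropRegressor(
        hidden_neurons=spec.hidden_neurons,
        max_epochs=spec.max_epochs,
        tol=spec.tol,
        patience=spec.patience,
        random_state=spec.seed,
    )
    return est.fit(train_X, train_y)


def evaluate(model, X, y) -> dict:
    """R^2, RMSE, and MRE (%) of a fitted model on (X, y)."""
    pred = model.predict(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    return {
        "R2": _metrics.r2(y, pred),
        "RMSE": _metrics.rmse(y, pred),
        "MRE": _metrics.mre(y, pred),
    }


_MODEL_FITTERS = {"ELM": fit_elm, "XGBoost": fit_xgb, "BPNN": fit_bpnn}


def run_matrix(
    features_table: pd.DataFrame,
    moisture,
    combinations: dict[str, FeatureCombination],
    split_spec: SplitSpec = SplitSpec(),
    elm: ElmSpec = ElmSpec(),
    xgb: XgbSpec = XgbSpec(),
    bpnn: BpnnSpec = BpnnSpec(),
) -> tuple[list[FitReport], pd.DataFrame]:
    """Fit every model on every combination; the comparison grid.

    Returns the list of :class:`FitReport` (one per model x combination)
    and a tidy results DataFrame (model, combination, split, R2, RMSE,
    MRE).  Empty combinations are refused: they are skipped with a
    warning and absent from the results.
    """
    y = np.asarray(moisture, dtype=float)
    if len(features_table) != y.size:
        raise ValueError("moisture length must match the feature table")
    train_idx, val_idx = split(y.size, split_spec)
    specs = {"ELM": elm, "XGBoost": xgb, "BPNN": bpnn}
    reports: list[FitReport] = []
    rows = []
    for cname, combo in combinations.items():
        if len(combo) == 0:
            warnings.warn(f"skipping {cname}: no features survived screening",
                          stacklevel=2)
            continue
        missing = [c for c in combo.columns if c not in features_table.columns]
        if missing:
            raise ValueError(f"{cname}: columns not in feature table: {missing}")
        X = features_table[list(combo.columns)].to_numpy(dtype=float)
        for mname, fitter in _MODEL_FITTERS.items():
            model = fitter(X[train_idx], y[train_idx], specs[mname])
            rep = FitReport(
                model=mname,
                combination=cname,
                train_pred=model.predict(X[train_idx]),
                val_pred=model.predict(X[val_idx]),
                metrics_train=evaluate(model, X[train_idx], y[train_idx]),
                metrics_val=evaluate(model, X[val_idx], y[val_idx]),
            )
            reports.append(rep)
            for sname, m in (("train", rep.metrics_train), ("validation", rep.metrics_val)):
                rows.append({"model": mname, "combination": cname, "split": sname, **m})
    return reports, pd.DataFrame(rows)
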