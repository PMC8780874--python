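"""Partial least squares regression (NIPALS, single response).

Predicts the adulterant mass fraction y (% w/w) from absorbance spectra.
X and y are mean-centered, never scaled (NIR convention).  For each latent
variable the weight vector maximizes covariance between X scores and y;
X is deflated by the rank-one score/loading product.  The fitted model is
exposed both as its latent decomposition and as a plain regression vector
plus intercept — the two prediction paths agree to machine precision.

Cross-validation is grouped (see :class:`CVScheme`): out-of-fold predictions
are pooled into a single PRESS, so R2CV = 1 - PRESS/TSS (TSS about the
global mean) and RMSECV = sqrt(PRESS/N).  The selected component count is
the global RMSECV minimum, ties to fewer components.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._cv import CVScheme, build_folds, group_ids
from .errors import DegenerateDataError, DimensionError, ParameterError
from .io import SpectraBlock

_EPS = 1e-14


@dataclass
class PLSModel:
    """Fitted PLS1 model with K latent variables."""

    n_components: int
    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray  # (P, K)
    x_loadings: np.ndarray  # (P, K)
    y_loadings: np.ndarray  # (K,)
    coef: np.ndarray  # (P,) regression vector
    intercept: float
    wavelengths: np.ndarray
    metrics: dict

    def predict_latent(self, X: np.ndarray) -> np.ndarray:
        """Prediction via the latent decomposition (internal cross-check)."""
        Xc = X - self.x_mean
        yhat = np.full(X.shape[0], self.y_mean)
        for k in range(self.n_components):
            t = Xc @ self.weights[:, k]
            yhat += self.y_loadings[k] * t
            Xc = Xc - np.outer(t, self.x_loadings[:, k])
        return yhat


def r_squared(y, yhat) -> float:
    """Coefficient of determination 1 - RSS/TSS."""
    y, yhat = np.asarray(y, float), np.asarray(yhat, float)
    tss = np.sum((y - y.mean()) ** 2)
    if tss <= 0:
        raise DegenerateDataError("R^2 undefined for constant y")
    return float(1.0 - np.sum((y - yhat) ** 2) / tss)


def rmse(y, yhat) -> float:
    """Root mean square error, in the units of y (% w/w here)."""
    y, yhat = np.asarray(y, float), np.asarray(yhat, float)
    if y.size == 0 or y.shape != yhat.shape:
        raise ParameterError("rmse needs two equal-length non-empty vectors")
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def _nipals(Xc: np.ndarray, yc: np.ndarray, k: int):
    """PLS1 NIPALS on centered data; returns W, P, q (may stop early)."""
    p_dim = Xc.shape[1]
    W = np.zeros((p_dim, k))
    P = np.zeros((p_dim, k))
    q = np.zeros(k)
    X_work, y_work = Xc.copy(), yc.copy()
    for j in range(k):
        w = X_work.T @ y_work
        norm = np.linalg.norm(w)
        if norm < _EPS:
            return W[:, :j], P[:, :j], q[:j]
        w /= norm
        t = X_work @ w
        tt = t @ t
        if tt < _EPS:
            return W[:, :j], P[:, :j], q[:j]
        p_vec = X_work.T @ t / tt
        q_j = y_work @ t / tt
        X_work -= np.outer(t, p_vec)
        y_work = y_work - q_j * t
        W[:, j], P[:, j], q[j] = w, p_vec, q_j
    return W, P, q


def fit_plsr(block: SpectraBlock, y, n_components: int) -> PLSModel:
    """Fit a PLS1 model with ``n_components`` latent variables."""
    X = block.absorbance
    y = np.asarray(y, dtype=float)
    if y.shape != (X.shape[0],):
        raise DimensionError("y length must equal the number of spectra")
    if np.ptp(y) == 0:
        raise DegenerateDataError("response y is constant")
    k_max = min(X.shape[0] - 1, X.shape[1])
    if not 1 <= n_components <= k_max:
        raise ParameterError(f"n_components must be in [1, {k_max}], got {n_components}")

    x_mean, y_mean = X.mean(axis=0), float(y.mean())
    W, P, q = _nipals(X - x_mean, y - y_mean, n_components)
    k_eff = W.shape[1]
    coef = W @ np.linalg.solve(P.T @ W, q)
    intercept = y_mean - x_mean @ coef

    yhat = intercept + X @ coef
    metrics = {"R2C": r_squared(y, yhat), "RMSEC": rmse(y, yhat)}
    return PLSModel(
        n_components=k_eff,
        x_mean=x_mean,
        y_mean=y_mean,
        weights=W,
        x_loadings=P,
        y_loadings=q,
        coef=coef,
        intercept=float(intercept),
        wavelengths=block.grid.values.copy(),
        metrics=metrics,
    )


def predict(model: PLSModel, block: SpectraBlock) -> np.ndarray:
    """yhat = intercept + A @ regression_vector."""
    if block.n_wavelengths != model.wavelengths.size or not np.allclose(
        block.grid.values, model.wavelengths
    ):
        raise DimensionError("block grid does not match the grid the PLS model was fit on")
    return model.intercept + block.absorbance @ model.coef


@dataclass
class CVResult:
    """Per-component-count cross-validation table and the selected K."""

    table: pd.DataFrame  # columns: n_components, R2C, RMSEC, R2CV, RMSECV
    selected: int
    predictions: np.ndarray  # pooled out-of-fold yhat at the selected K

    def row(self, k: int) -> pd.Series:
        return self.table.set_index("n_components").loc[k]


def cross_validate(
    block: SpectraBlock, y, scheme: CVScheme, max_components: int
) -> CVResult:
    """Grouped CV of PLS1 over component counts 1..max_components.

    Centering (and the model itself) is refit on each calibration fold; the
    validation fold only ever passes through ``predict``.
    """
    y = np.asarray(y, dtype=float)
    folds = build_folds(block.meta, scheme)
    n = block.n_spectra
    press = np.zeros(max_components)
    oof = np.zeros((max_components, n))
    for fold in folds:
        val_mask = np.zeros(n, dtype=bool)
        val_mask[fold] = True
        y_train = y[~val_mask]
        if np.ptp(y_train) == 0:
            raise DegenerateDataError("a calibration fold has constant y")
        train = block.select(~val_mask)
        val = block.select(val_mask)
        k_fold = min(max_components, train.n_spectra - 1, train.n_wavelengths)
        model = fit_plsr(train, y_train, k_fold)
        # predictions for every K from the same NIPALS pass
        Xc = val.absorbance - model.x_mean
        yhat = np.full(val.n_spectra, model.y_mean)
        for k in range(max_components):
            if k < model.n_components:
                t = Xc @ model.weights[:, k]
                yhat = yhat + model.y_loadings[k] * t
                Xc = Xc - np.outer(t, model.x_loadings[:, k])
            oof[k, val_mask] = yhat
            press[k] += np.sum((y[val_mask] - yhat) ** 2)

    tss = np.sum((y - y.mean()) ** 2)
    rows = []
    for k in range(1, max_components + 1):
        cal = fit_plsr(block, y, k)
        rows.append(
            {
                "n_components": k,
                "R2C": cal.metrics["R2C"],
                "RMSEC": cal.metrics["RMSEC"],
                "R2CV": 1.0 - press[k - 1] / tss,
                "RMSECV": float(np.sqrt(press[k - 1] / n)),
            }
        )
    table = pd.DataFrame(rows)
    selected = int(table.loc[table["RMSECV"].round(12).idxmin(), "n_components"])
    return CVResult(table=table, selected=selected, predictions=oof[selected - 1])


def scan_triplet_scheme() -> CVScheme:
    """Leave one group out, a group being the consecutive scans of one
    replicate refill (a 'scan triplet')."""
    return CVScheme(kind="leave_group_out", group_key=("replicate", "refill"))


__all__ = [
    "PLSModel",
    "CVResult",
    "CVScheme",
    "fit_plsr",
    "predict",
    "cross_validate",
    "r_squared",
    "rmse",
    "scan_triplet_scheme",
    "group_ids",
]
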