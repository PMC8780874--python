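"""Hybrid PCA-LDA multi-class classification with grouped cross-validation.

The classifier projects spectra onto the first NrPCs principal components
and applies linear discriminant analysis in score space: with equal class
priors and a pooled within-class covariance (plus a small ridge for stable
inversion), assignment is to the class whose centroid is nearest in
Mahalanobis distance — the standard linear discriminant rule.

NrPC selection follows a two-criterion rule: among candidate counts whose
cross-validated (prediction) accuracy is within a tolerance of the best,
pick the one minimizing the gap between training (recognition) and
validation accuracy; ties go to the smaller count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import solve_triangular

from ._cv import CVScheme, build_folds
from .errors import DegenerateDataError, ParameterError
from .io import SpectraBlock
from .pca import PCAModel, fit_pca, project


@dataclass
class PCALDAModel:
    """Fitted PCA-LDA classifier."""

    pca: PCAModel
    class_labels: np.ndarray  # ordered categories
    class_means: np.ndarray  # (C, NrPCs) score-space centroids
    pooled_within_cov: np.ndarray  # (NrPCs, NrPCs), ridge-regularized
    discriminant_basis: np.ndarray  # (NrPCs, min(NrPCs, C-1)) directions
    ridge: float

    @property
    def nrpcs(self) -> int:
        return self.pca.n_components


@dataclass
class ConfusionResult:
    """Row-normalized confusion matrix plus the two headline accuracies.

    ``matrix`` rows are true classes, columns assigned classes, in percent
    (each row sums to 100).  ``recognition_accuracy`` is the mean calibration
    accuracy over folds; ``prediction_accuracy`` the pooled validation
    accuracy.
    """

    labels: np.ndarray
    matrix: np.ndarray
    counts: np.ndarray
    recognition_accuracy: float
    prediction_accuracy: float
    fold_train_accuracies: list = None  # per-fold calibration accuracy, %
    assignments: np.ndarray = None  # pooled out-of-fold assigned label per row

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.labels, columns=self.labels)


def _class_order(labels: np.ndarray) -> np.ndarray:
    return pd.unique(pd.Series(labels))


def fit_pcalda(
    block: SpectraBlock, labels, nrpcs: int, ridge: float | None = None
) -> PCALDAModel:
    """Fit PCA (NrPCs components) then LDA on the scores."""
    labels = np.asarray(labels)
    order = _class_order(labels)
    if order.size < 2:
        raise DegenerateDataError("PCA-LDA needs at least two classes")
    counts = pd.Series(labels).value_counts()
    if counts.min() < 2:
        raise DegenerateDataError("every class needs at least two spectra")
    pca = fit_pca(block, nrpcs)
    T = project(pca, block)

    means = np.vstack([T[labels == c].mean(axis=0) for c in order])
    sw = np.zeros((nrpcs, nrpcs))
    for c, mu in zip(order, means):
        D = T[labels == c] - mu
        sw += D.T @ D
    sw /= max(len(labels) - order.size, 1)
    if ridge is None:
        # floor keeps the Cholesky factorization valid on exactly noiseless data
        ridge = max(1e-8 * np.trace(sw) / nrpcs, 1e-12)
    sw_r = sw + ridge * np.eye(nrpcs)

    # between-class scatter (equal priors) for the discriminant directions
    grand = means.mean(axis=0)
    sb = (means - grand).T @ (means - grand) / order.size
    evals, evecs = np.linalg.eigh(np.linalg.solve(sw_r, sb + sb.T) / 2.0)
    n_dir = min(nrpcs, order.size - 1)
    basis = evecs[:, np.argsort(evals)[::-1][:n_dir]]

    return PCALDAModel(
        pca=pca,
        class_labels=order,
        class_means=means,
        pooled_within_cov=sw_r,
        discriminant_basis=basis,
        ridge=float(ridge),
    )


def predict_pcalda(model: PCALDAModel, block: SpectraBlock) -> np.ndarray:
    """Assign each spectrum to the nearest class centroid (Mahalanobis)."""
    T = project(model.pca, block)
    L = np.linalg.cholesky(model.pooled_within_cov)
    # squared Mahalanobis distance to each centroid via triangular solves
    d2 = np.empty((T.shape[0], model.class_means.shape[0]))
    for j, mu in enumerate(model.class_means):
        w = solve_triangular(L, (T - mu).T, lower=True)
        d2[:, j] = np.sum(w**2, axis=0)
    return model.class_labels[np.argmin(d2, axis=1)]


def crossvalidate_pcalda(
    block: SpectraBlock,
    labels,
    scheme: CVScheme,
    nrpcs: int,
    seed: int | None = None,
    ridge: float | None = None,
) -> ConfusionResult:
    """Grouped, stratified k-fold CV of the PCA-LDA classifier.

    All rows of one group (e.g. a replicate with all its refills and scans)
    stay in one fold.  The validation confusion matrix is pooled over folds.
    """
    labels = np.asarray(labels)
    order = _class_order(labels)
    folds = build_folds(block.meta, scheme, labels=labels, seed=seed)
    pos = {c: i for i, c in enumerate(order)}
    counts = np.zeros((order.size, order.size), dtype=float)
    train_accs = []
    assignments = np.empty(block.n_spectra, dtype=object)
    for fold in folds:
        val_mask = np.zeros(block.n_spectra, dtype=bool)
        val_mask[fold] = True
        train = block.select(~val_mask)
        model = fit_pcalda(train, labels[~val_mask], nrpcs, ridge=ridge)
        train_accs.append(100.0 * np.mean(predict_pcalda(model, train) == labels[~val_mask]))
        pred = predict_pcalda(model, block.select(val_mask))
        assignments[val_mask] = pred
        for t, p in zip(labels[val_mask], pred):
            counts[pos[t], pos[p]] += 1
    row_sums = counts.sum(axis=1, keepdims=True)
    matrix = 100.0 * counts / np.where(row_sums == 0, 1, row_sums)
    return ConfusionResult(
        labels=order,
        matrix=matrix,
        counts=counts,
        recognition_accuracy=float(np.mean(train_accs)),
        prediction_accuracy=100.0 * float(np.trace(counts) / counts.sum()),
        fold_train_accuracies=[float(a) for a in train_accs],
        assignments=assignments,
    )


def apply_selection_rule(candidates, tolerance_pp: float = 1.0) -> int:
    """The NrPC selection rule on precomputed accuracies.

    ``candidates`` is a list of (nrpcs, training_accuracy,
    validation_accuracy).  Among candidates whose validation accuracy is
    within ``tolerance_pp`` percentage points of the best, pick the one
    minimizing the training-validation gap; ties go to the smaller NrPCs.
    """
    if not candidates:
        raise ParameterError("empty NrPC candidate range")
    best_val = max(v for _, _, v in candidates)
    eligible = [c for c in candidates if c[2] >= best_val - tolerance_pp]
    return min(eligible, key=lambda c: (c[1] - c[2], c[0]))[0]


def select_nrpcs(
    block: SpectraBlock,
    labels,
    scheme: CVScheme,
    candidate_range,
    seed: int | None = None,
    tolerance_pp: float = 1.0,
) -> int:
    """Pick NrPCs by cross-validating each candidate and applying
    :func:`apply_selection_rule`."""
    candidates = sorted(set(int(c) for c in candidate_range))
    if not candidates:
        raise ParameterError("empty NrPC candidate range")
    results = []
    for k in candidates:
        res = crossvalidate_pcalda(block, labels, scheme, k, seed=seed)
        results.append((k, res.recognition_accuracy, res.prediction_accuracy))
    return apply_selection_rule(results, tolerance_pp)


__all__ = [
    "PCALDAModel",
    "ConfusionResult",
    "fit_pcalda",
    "predict_pcalda",
    "crossvalidate_pcalda",
    "apply_selection_rule",
    "select_nrpcs",
    "CVScheme",
]
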