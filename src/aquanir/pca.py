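"""Principal component analysis via SVD of the mean-centered matrix.

Spectra share units, so columns are mean-centered only (no scaling).  The
sign of each loading is fixed so its largest-magnitude element is positive,
making scores and loadings reproducible across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DimensionError, ParameterError
from .io import SpectraBlock


@dataclass
class PCAModel:
    """Fitted PCA: column means, orthonormal loadings, variance ratios."""

    mean: np.ndarray
    loadings: np.ndarray  # (P, K), orthonormal columns
    explained_variance: np.ndarray  # (K,) eigenvalues of the covariance (ddof=1)
    explained_variance_ratio: np.ndarray  # (K,), fractions of total variance
    wavelengths: np.ndarray  # grid the model was fit on

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]


def fit_pca(block: SpectraBlock, n_components: int) -> PCAModel:
    """Fit PCA with ``n_components`` <= min(N-1, P)."""
    X = block.absorbance
    n, p = X.shape
    k_max = min(n - 1, p)
    if not 1 <= n_components <= k_max:
        raise ParameterError(f"n_components must be in [1, {k_max}], got {n_components}")
    mean = X.mean(axis=0)
    Xc = X - mean
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    loadings = vt[:n_components].T
    # sign convention: largest |element| of each loading is positive
    flip = np.sign(loadings[np.abs(loadings).argmax(axis=0), np.arange(n_components)])
    flip[flip == 0] = 1.0
    loadings = loadings * flip
    eig = s**2 / (n - 1)
    total = eig.sum()
    ratio = eig[:n_components] / total if total > 0 else np.zeros(n_components)
    return PCAModel(
        mean=mean,
        loadings=loadings,
        explained_variance=eig[:n_components],
        explained_variance_ratio=ratio,
        wavelengths=block.grid.values.copy(),
    )


def project(model: PCAModel, block: SpectraBlock) -> np.ndarray:
    """Scores (N x K) of a block on a fitted model: (A - mean) @ loadings."""
    if block.n_wavelengths != model.wavelengths.size or not np.allclose(
        block.grid.values, model.wavelengths
    ):
        raise DimensionError("block grid does not match the grid the PCA was fit on")
    return (block.absorbance - model.mean) @ model.loadings


__all__ = ["PCAModel", "fit_pca", "project"]
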