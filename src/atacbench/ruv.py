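"""Removal of unwanted variation from peak-count matrices (RUVr-style).

Unwanted factors (batch, depth, handling) are estimated by factor analysis
of the residuals of a per-peak linear model of log2-CPM on the known
condition design: the first k left singular vectors of the sample-side
residual matrix span the unwanted subspace.  Because the residuals are
orthogonal to the design, regressing log2-CPM on those factors and
subtracting the fit removes unwanted structure while preserving the
condition signal.  Corrected counts are obtained by inverting the log2-CPM
transform at the original library sizes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

from .da import logcpm_transform

__all__ = [
    "FactorModel",
    "residual_matrix",
    "ruvr_correct",
    "correct_logcpm",
    "pca_diagnostic",
    "effective_library_sizes",
]


@dataclass
class FactorModel:
    """Estimated unwanted variation: orthonormal sample factors and loadings."""

    W: np.ndarray  # samples x k, orthonormal columns
    alpha: np.ndarray  # k x peaks
    k: int


def _design_matrix(condition: np.ndarray) -> np.ndarray:
    condition = np.asarray(condition)
    levels = list(dict.fromkeys(condition))
    X = np.column_stack(
        [np.ones(len(condition))]
        + [(condition == lev).astype(float) for lev in levels[1:]]
    )
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("condition design is rank deficient")
    return X


def effective_library_sizes(counts: np.ndarray, norm: str = "colsum") -> np.ndarray:
    """Library sizes as column sums (default) or upper-quartile scaled."""
    counts = np.asarray(counts, dtype=float)
    colsum = counts.sum(axis=0)
    if norm == "colsum":
        return colsum
    if norm == "upperquartile":
        uq = np.array(
            [np.percentile(col[col > 0], 75) if (col > 0).any() else 0.0 for col in counts.T]
        )
        if (uq <= 0).any():
            raise ValueError("upper-quartile normalization undefined for an all-zero sample")
        return uq / uq.mean() * colsum.mean()
    raise ValueError(f"unknown norm {norm!r}")


def residual_matrix(
    counts: np.ndarray,
    condition: np.ndarray,
    library_sizes: np.ndarray | None = None,
    prior_count: float = 2.0,
    norm: str = "colsum",
) -> np.ndarray:
    """Per-peak least-squares residuals of log2-CPM on the condition design.

    Returns a peaks x samples matrix orthogonal to the design columns (for
    a two-group design these are simply the within-group mean deviations).
    """
    counts = np.asarray(counts, dtype=float)
    if library_sizes is None:
        library_sizes = effective_library_sizes(counts, norm=norm)
    y = logcpm_transform(counts, library_sizes, prior_count)
    X = _design_matrix(condition)
    hat = X @ np.linalg.inv(X.T @ X) @ X.T
    return y - y @ hat.T


def _unwanted_factors(residuals: np.ndarray, k: int) -> np.ndarray:
    """First k left singular vectors of the sample-side residual matrix."""
    n_samples = residuals.shape[1]
    if not 0 <= k < n_samples:
        raise ValueError(f"k must satisfy 0 <= k < n_samples, got {k}")
    if k == 0:
        return np.zeros((n_samples, 0))
    E = residuals.T  # samples x peaks; rows already centered by the design fit
    U, s, _ = np.linalg.svd(E, full_matrices=False)
    W = U[:, :k]
    # reproducible sign: largest-magnitude entry of each column positive
    for j in range(k):
        i = np.argmax(np.abs(W[:, j]))
        if W[i, j] < 0:
            W[:, j] = -W[:, j]
    return W


def correct_logcpm(
    logcpm: np.ndarray,
    condition: np.ndarray,
    k: int,
    residuals: np.ndarray | None = None,
) -> tuple[np.ndarray, FactorModel]:
    """Remove k unwanted factors from a log2-CPM matrix (peaks x samples)."""
    logcpm = np.asarray(logcpm, dtype=float)
    if residuals is None:
        X = _design_matrix(condition)
        hat = X @ np.linalg.inv(X.T @ X) @ X.T
        residuals = logcpm - logcpm @ hat.T
    W = _unwanted_factors(residuals, k)
    # W columns are orthonormal and orthogonal to the design, so per-peak
    # OLS of logCPM on W reduces to a projection
    alpha = W.T @ logcpm.T  # k x peaks
    corrected = logcpm - (W @ alpha).T
    return corrected, FactorModel(W=W, alpha=alpha, k=k)


def ruvr_correct(
    counts: np.ndarray,
    condition: np.ndarray,
    k: int = 3,
    residuals: np.ndarray | None = None,
    library_sizes: np.ndarray | None = None,
    prior_count: float = 2.0,
    norm: str = "colsum",
) -> tuple[np.ndarray, FactorModel]:
    """RUVr-style correction of a count matrix.

    Estimates k unwanted factors from model residuals, removes them on the
    log2-CPM scale, and back-transforms to integer counts at the original
    library sizes (rounded, clamped at zero).
    """
    counts = np.asarray(counts, dtype=float)
    if library_sizes is None:
        library_sizes = effective_library_sizes(counts, norm=norm)
    library_sizes = np.asarray(library_sizes, dtype=float)
    y = logcpm_transform(counts, library_sizes, prior_count)
    if residuals is None:
        residuals = residual_matrix(
            counts, condition, library_sizes=library_sizes, prior_count=prior_count
        )
    corrected_y, model = correct_logcpm(y, condition, k, residuals=residuals)
    prior = prior_count * library_sizes / library_sizes.mean()
    raw = 2.0**corrected_y / 1e6 * (library_sizes + 2.0 * prior) - prior
    corrected_counts = np.rint(np.clip(raw, 0.0, None)).astype(np.int64)
    return corrected_counts, model


def pca_diagnostic(
    counts: np.ndarray,
    n_components: int = 2,
    library_sizes: np.ndarray | None = None,
    prior_count: float = 2.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample scores on the first principal components of centered log2-CPM.

    Returns (scores: samples x n_components, explained variance ratio);
    deterministic up to the fixed sign convention.
    """
    counts = np.asarray(counts, dtype=float)
    n_samples = counts.shape[1]
    if n_samples < 3:
        raise ValueError("PCA diagnostic needs at least 3 samples")
    if n_components > n_samples:
        raise ValueError("more components than samples requested")
    y = logcpm_transform(counts, library_sizes, prior_count)
    centered = (y - y.mean(axis=1, keepdims=True)).T  # samples x peaks
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(centered)
    for j in range(scores.shape[1]):
        i = np.argmax(np.abs(scores[:, j]))
        if scores[i, j] < 0:
            scores[:, j] = -scores[:, j]
    return scores, pca.explained_variance_ratio_
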