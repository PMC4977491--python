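"""Shape ordination: total-variance PCA, between-group PCA, allometry.

Total PCA eigen-decomposes the sample covariance of tangent coordinates.
Between-group PCA (bgPCA) instead uses the covariance of the group mean
vectors (weighted by group size) and projects *all* specimens onto those
axes, emphasizing among-group differences; with g groups at most g - 1
eigenvalues are nonzero.  Allometry is assessed by ordinary least squares
of PC scores on centroid size.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class ShapeOrdination:
    """Scores, axes and spectrum of a shape-space ordination."""

    scores: np.ndarray  # (n, p)
    eigenvectors: np.ndarray  # (3k, p), orthonormal columns
    eigenvalues: np.ndarray  # (p,), descending
    variance_fraction: np.ndarray  # (p,)
    kind: str  # "total" | "between_group"
    mean_vector: np.ndarray  # (3k,)
    group_labels: np.ndarray | None = None
    total_variance: float | None = None  # trace of the full covariance

    @property
    def p(self) -> int:
        return len(self.eigenvalues)


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    """Make each eigenvector's largest-magnitude entry positive (plot stability)."""
    vectors = vectors.copy()
    for j in range(vectors.shape[1]):
        i = int(np.argmax(np.abs(vectors[:, j])))
        if vectors[i, j] < 0:
            vectors[:, j] = -vectors[:, j]
    return vectors


def total_pca(tangent: np.ndarray) -> ShapeOrdination:
    """PCA of the total variance-covariance matrix of tangent coordinates."""
    tangent = np.asarray(tangent, dtype=float)
    n = tangent.shape[0]
    if n < 2:
        raise ValueError("need at least two specimens")
    mean = tangent.mean(axis=0)
    centered = tangent - mean
    # SVD route: covariance eigenvectors without forming the 3k x 3k matrix
    _, svals, vt = np.linalg.svd(centered, full_matrices=False)
    eigvals = svals**2 / (n - 1)
    keep = eigvals > max(eigvals[0], 1e-300) * 1e-12
    eigvals = eigvals[keep]
    vecs = _fix_signs(vt[keep].T)
    total_var = float(centered.var(axis=0, ddof=1).sum())
    return ShapeOrdination(
        scores=centered @ vecs,
        eigenvectors=vecs,
        eigenvalues=eigvals,
        variance_fraction=eigvals / total_var,
        kind="total",
        mean_vector=mean,
        total_variance=total_var,
    )


def retain_for_variance(ordn: ShapeOrdination, threshold: float = 0.95) -> np.ndarray:
    """Leading PC scores whose cumulative variance fraction reaches ``threshold``."""
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    cum = np.cumsum(ordn.variance_fraction)
    q = int(np.searchsorted(cum, threshold - 1e-12) + 1)
    q = min(q, ordn.p)
    return ordn.scores[:, :q]


def between_group_pca(
    tangent: np.ndarray, groups: Sequence[str]
) -> ShapeOrdination:
    """PCA of the between-groups covariance, with all specimens projected.

    Group means are weighted by group size n_g with divisor n - 1, so that
    when every specimen is its own group the result coincides with the
    total-variance PCA.  Variance fractions are reported relative to the
    between-group variance; ``total_variance`` holds the total for fractions
    of total variance.
    """
    tangent = np.asarray(tangent, dtype=float)
    groups = np.asarray(groups)
    labels, inverse, counts = np.unique(groups, return_inverse=True, return_counts=True)
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    if (counts == 0).any():
        raise ValueError("empty group")
    n = tangent.shape[0]
    grand = tangent.mean(axis=0)
    means = np.stack([tangent[inverse == g].mean(axis=0) for g in range(len(labels))])
    weighted = (means - grand) * np.sqrt(counts)[:, None]
    _, svals, vt = np.linalg.svd(weighted / np.sqrt(n - 1), full_matrices=False)
    eigvals = svals**2
    keep = eigvals > max(eigvals[0], 1e-300) * 1e-10
    eigvals = eigvals[keep]
    vecs = _fix_signs(vt[keep].T)
    total_var = float(((tangent - grand) ** 2).sum() / (n - 1))
    return ShapeOrdination(
        scores=(tangent - grand) @ vecs,
        eigenvectors=vecs,
        eigenvalues=eigvals,
        variance_fraction=eigvals / eigvals.sum(),
        kind="between_group",
        mean_vector=grand,
        group_labels=groups,
        total_variance=total_var,
    )


def shape_at_score(
    ordn: ShapeOrdination, axis: int, score: float, k: int
) -> np.ndarray:
    """Configuration at a given score along one ordination axis.

    ``shape_at_score(ordn, axis, 0, k)`` is the mean shape; axis-extreme
    shapes visualize the shape changes each axis encodes.
    """
    if axis >= ordn.p:
        raise ValueError(f"axis {axis} out of range (p={ordn.p})")
    vec = ordn.mean_vector + score * ordn.eigenvectors[:, axis]
    return vec.reshape(k, 3)


def allometry_regression(
    scores: np.ndarray, centroid_sizes: np.ndarray, log_size: bool = False
) -> tuple[pd.DataFrame, float]:
    """OLS of each retained PC score on centroid size.

    Returns a per-axis table (slope, R^2, two-sided p) and a multivariate
    summary R^2: trace of the predicted-score covariance over trace of the
    total score covariance.
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    cs = np.asarray(centroid_sizes, dtype=float)
    if log_size:
        cs = np.log(cs)
    if len(cs) < 3:
        raise ValueError("need at least 3 specimens")
    if np.ptp(cs) < 1e-12 or np.var(cs) < 1e-24:
        raise ValueError("centroid size has zero variance")
    rows = []
    predicted = np.empty_like(scores)
    for j in range(scores.shape[1]):
        res = stats.linregress(cs, scores[:, j])
        rows.append(
            {"axis": j + 1, "slope": res.slope, "r_squared": res.rvalue**2,
             "p_value": res.pvalue}
        )
        predicted[:, j] = res.intercept + res.slope * cs
    total = np.trace(np.cov(scores, rowvar=False, ddof=1).reshape(scores.shape[1], -1))
    pred = np.trace(np.cov(predicted, rowvar=False, ddof=1).reshape(scores.shape[1], -1))
    return pd.DataFrame(rows), float(pred / total)
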