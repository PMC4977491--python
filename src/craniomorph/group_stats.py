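"""Among-group statistics: size ANOVA + Tukey HSD, MANOVA, Mahalanobis distances.

Size differences are tested by one-way ANOVA on centroid size with
Tukey's honestly-significant-difference pairwise comparisons
(Tukey-Kramer for unbalanced designs).  Shape differences among groups
are tested by MANOVA on the retained PC scores using Wilks' lambda with
Rao's F approximation (Pillai's trace available), with an effect-size
R^2 = trace(B)/trace(T) over the between-group and total sums-of-squares
matrices (1 - lambda available as an alternative).  Biodistances are
Mahalanobis distances between group mean score vectors standardized by
the pooled within-group covariance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd


def _group_split(values: np.ndarray, groups: Sequence[str]):
    groups = np.asarray(groups)
    labels, inverse, counts = np.unique(groups, return_inverse=True, return_counts=True)
    return labels, inverse, counts


def size_anova(cs: np.ndarray, groups: Sequence[str]) -> tuple[float, float]:
    """One-way ANOVA of centroid size on group; returns (F, p)."""
    cs = np.asarray(cs, dtype=float)
    labels, inverse, counts = _group_split(cs, groups)
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    if (counts < 2).any():
        bad = labels[counts < 2]
        raise ValueError(f"groups with fewer than 2 members: {list(bad)}")
    samples = [cs[inverse == g] for g in range(len(labels))]
    f, p = stats.f_oneway(*samples)
    return float(f), float(p)


def tukey_hsd(
    cs: np.ndarray, groups: Sequence[str], alpha: float = 0.05
) -> pd.DataFrame:
    """All-pairs Tukey HSD on centroid size (Tukey-Kramer when unbalanced).

    Returns a table with group pair, mean difference, confidence interval,
    adjusted p-value and a rejection flag at ``alpha``.
    """
    cs = np.asarray(cs, dtype=float)
    labels, inverse, counts = _group_split(cs, groups)
    if (counts < 2).any():
        raise ValueError("every group needs at least 2 members")
    res = pairwise_tukeyhsd(cs, np.asarray(groups), alpha=alpha)
    table = pd.DataFrame(
        res.summary().data[1:],
        columns=[c.strip() for c in res.summary().data[0]],
    )
    table = table.rename(
        columns={"group1": "group_a", "group2": "group_b", "meandiff": "diff",
                 "p-adj": "p_adj", "lower": "ci_low", "upper": "ci_high"}
    )
    for col in ("diff", "p_adj", "ci_low", "ci_high"):
        table[col] = table[col].astype(float)
    table["reject"] = table["reject"].astype(bool)
    return table


@dataclass
class ManovaResult:
    """Wilks' lambda MANOVA with a trace-based effect-size R^2."""

    wilks_lambda: float
    F_approx: float
    df: tuple[float, float]
    p_value: float
    r_squared: float  # trace(B)/trace(T)
    r_squared_wilks: float  # 1 - lambda
    pillai: float
    grouping: str = ""
    subset: str = "all"
    q_used: int = 0


def _sums_of_squares(scores: np.ndarray, inverse: np.ndarray, n_groups: int):
    grand = scores.mean(axis=0)
    total = scores - grand
    T = total.T @ total
    W = np.zeros_like(T)
    for g in range(n_groups):
        block = scores[inverse == g]
        centered = block - block.mean(axis=0)
        W += centered.T @ centered
    B = T - W
    return B, W, T


def manova(
    scores: np.ndarray, groups: Sequence[str], grouping: str = "", subset: str = "all"
) -> ManovaResult:
    """MANOVA of score vectors on a grouping factor.

    Wilks' lambda = det(W)/det(W+B) with Rao's F approximation.  If the
    within-group degrees of freedom cannot support the score dimension
    (n - g <= q), trailing score columns are dropped with a warning.
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    if scores.shape[0] < scores.shape[1] and scores.ndim == 2 and scores.shape[0] == 1:
        scores = scores.T
    groups = np.asarray(groups)
    labels, inverse, counts = np.unique(groups, return_inverse=True, return_counts=True)
    n, q = scores.shape
    g = len(labels)
    if g < 2:
        raise ValueError("need at least two groups")
    if n - g <= q:
        import warnings

        q_new = n - g - 1
        if q_new < 1:
            raise ValueError("too few specimens for any MANOVA dimension")
        warnings.warn(
            f"reducing score dimension from {q} to {q_new} so the within-group "
            "covariance is invertible"
        )
        scores = scores[:, :q_new]
        q = q_new
    B, W, T = _sums_of_squares(scores, inverse, g)
    sign_w, logdet_w = np.linalg.slogdet(W)
    sign_t, logdet_t = np.linalg.slogdet(T)
    if sign_w <= 0 or sign_t <= 0:
        raise np.linalg.LinAlgError("singular within or total covariance in MANOVA")
    lam = float(np.exp(logdet_w - logdet_t))

    # Rao's F approximation for Wilks' lambda
    p, h, e = q, g - 1, n - g  # dims, hypothesis df, error df
    if p**2 + h**2 - 5 > 0:
        t = np.sqrt((p**2 * h**2 - 4) / (p**2 + h**2 - 5))
    else:
        t = 1.0
    w = e + h - (p + h + 1) / 2
    df1 = p * h
    df2 = w * t - (p * h - 2) / 2
    lam_t = lam ** (1 / t)
    F = (1 - lam_t) / lam_t * df2 / df1
    p_value = float(stats.f.sf(F, df1, df2))

    eigs = np.linalg.eigvals(np.linalg.solve(W, B)).real
    pillai = float(np.sum(eigs / (1 + eigs)))
    return ManovaResult(
        wilks_lambda=lam,
        F_approx=float(F),
        df=(float(df1), float(df2)),
        p_value=p_value,
        r_squared=float(np.trace(B) / np.trace(T)),
        r_squared_wilks=1.0 - lam,
        pillai=pillai,
        grouping=grouping,
        subset=subset,
        q_used=q,
    )


@dataclass
class GroupDistanceMatrix:
    """Symmetric among-group distance matrix with labels."""

    labels: tuple[str, ...]
    D: np.ndarray

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, dtype=float)
        g = len(self.labels)
        if self.D.shape != (g, g):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(self.D, self.D.T, atol=1e-8):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.D), 0, atol=1e-8):
            raise ValueError("distance matrix must have zero diagonal")
        if (self.D < -1e-12).any():
            raise ValueError("distances must be nonnegative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.D, index=self.labels, columns=self.labels)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="group")

    @classmethod
    def from_tsv(cls, path) -> "GroupDistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(labels=tuple(df.index), D=df.to_numpy(dtype=float))


def load_published_cultural_distances(anatomical_unit: str) -> GroupDistanceMatrix:
    """Published among-group Mahalanobis matrix for the five cultural horizons.

    Fixed input (printed values) used for tree construction; one matrix per
    anatomical unit ("cranium" or "mandible").
    """
    from importlib.resources import files

    path = files("craniomorph") / "data" / f"cultural_mahalanobis_{anatomical_unit}.tsv"
    return GroupDistanceMatrix.from_tsv(str(path))


def mahalanobis_matrix(
    scores: np.ndarray, groups: Sequence[str]
) -> GroupDistanceMatrix:
    """Pairwise Mahalanobis distances between group means.

    D[i, j] = sqrt((m_i - m_j)' W^-1 (m_i - m_j)) with W the pooled
    within-group covariance (divisor n - g).  Distances are unsquared.
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    groups = np.asarray(groups)
    labels, inverse, counts = np.unique(groups, return_inverse=True, return_counts=True)
    n, q = scores.shape
    g = len(labels)
    if n - g <= q - 1 or n - g < 1:
        raise ValueError(
            f"pooled within-group covariance not invertible (n-g={n - g}, q={q}); "
            "retain fewer PCs"
        )
    _, W_ss, _ = _sums_of_squares(scores, inverse, g)
    W = W_ss / (n - g)
    means = np.stack([scores[inverse == g_].mean(axis=0) for g_ in range(g)])
    try:
        chol = np.linalg.cholesky(W)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "singular pooled within-group covariance; retain fewer PCs"
        ) from exc
    D = np.zeros((g, g))
    for i in range(g):
        for j in range(i + 1, g):
            diff = means[i] - means[j]
            z = np.linalg.solve(chol, diff)
            D[i, j] = D[j, i] = np.sqrt(z @ z)
    return GroupDistanceMatrix(labels=tuple(labels), D=D)
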