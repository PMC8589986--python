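"""Multivariate differentiation: z-scored Euclidean distances,
permutational MANOVA, homogeneity-of-dispersion test, and PCA with the
broken-stick significance rule."""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .features import STARRED_COLUMNS

__all__ = [
    "PermutationTestResult",
    "PcaResult",
    "zscore_and_distance",
    "permanova",
    "permdisp",
    "pca_broken_stick",
    "broken_stick",
]


@dataclass
class PermutationTestResult:
    statistic: float
    p_value: float
    n_permutations: int
    df_between: int
    df_within: int


@dataclass
class PcaResult:
    eigenvalues: np.ndarray
    proportions: np.ndarray
    loadings: np.ndarray
    scores: np.ndarray
    broken_stick: np.ndarray
    significant: np.ndarray


def zscore_and_distance(
    table: pd.DataFrame, variable_subset: tuple[str, ...] = STARRED_COLUMNS
) -> np.ndarray:
    """Column-wise z-score then pairwise Euclidean distance matrix."""
    X = table[list(variable_subset)].to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = [variable_subset[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"zero-variance columns: {bad}")
    Z = (X - X.mean(axis=0)) / sd
    return squareform(pdist(Z, metric="euclidean"))


def _group_indices(labels: np.ndarray) -> list[np.ndarray]:
    labels = np.asarray(labels)
    return [np.flatnonzero(labels == g) for g in np.unique(labels)]


def _pseudo_f(d2: np.ndarray, groups: list[np.ndarray], n: int) -> float:
    """Pseudo-F from squared distances (between/within sums of squares)."""
    ss_total = d2[np.triu_indices(n, k=1)].sum() / n
    ss_within = 0.0
    for idx in groups:
        if idx.size > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(idx.size, k=1)].sum() / idx.size
    ss_between = ss_total - ss_within
    k = len(groups)
    df_b, df_w = k - 1, n - k
    if ss_within <= 0:
        return np.inf if ss_between > 0 else 0.0
    return (ss_between / df_b) / (ss_within / df_w)


def permanova(
    dist: np.ndarray,
    labels: np.ndarray,
    n_perm: int = 999,
    rng: np.random.Generator | None = None,
) -> PermutationTestResult:
    """Permutational multivariate ANOVA on a distance matrix.

    ``p = (count of permuted F >= observed F + 1) / (n_perm + 1)``.
    """
    labels = np.asarray(labels)
    n = dist.shape[0]
    if np.unique(labels).size < 2:
        raise ValueError("permanova needs at least two groups")
    rng = rng if rng is not None else np.random.default_rng()
    d2 = np.asarray(dist, dtype=float) ** 2
    groups = _group_indices(labels)
    f_obs = _pseudo_f(d2, groups, n)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        if _pseudo_f(d2, _group_indices(perm), n) >= f_obs:
            count += 1
    k = len(groups)
    return PermutationTestResult(
        statistic=float(f_obs),
        p_value=(count + 1) / (n_perm + 1),
        n_permutations=n_perm,
        df_between=k - 1,
        df_within=n - k,
    )


def _pcoa_coordinates(dist: np.ndarray) -> np.ndarray:
    """Principal-coordinate embedding of a distance matrix."""
    n = dist.shape[0]
    d2 = np.asarray(dist, dtype=float) ** 2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ d2 @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    keep = vals > 1e-10
    return vecs[:, keep] * np.sqrt(vals[keep])


def centroid_distances(dist: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Distance of each point to its group centroid in PCoA space."""
    labels = np.asarray(labels)
    coords = _pcoa_coordinates(dist)
    out = np.empty(dist.shape[0])
    for idx in _group_indices(labels):
        centroid = coords[idx].mean(axis=0)
        out[idx] = np.linalg.norm(coords[idx] - centroid, axis=1)
    return out


def _anova_f(values: np.ndarray, groups: list[np.ndarray]) -> float:
    n = values.size
    k = len(groups)
    grand = values.mean()
    ss_b = sum(idx.size * (values[idx].mean() - grand) ** 2 for idx in groups)
    ss_w = sum(((values[idx] - values[idx].mean()) ** 2).sum() for idx in groups)
    if ss_w <= 0:
        return np.inf if ss_b > 0 else 0.0
    return (ss_b / (k - 1)) / (ss_w / (n - k))


def permdisp(
    dist: np.ndarray,
    labels: np.ndarray,
    n_perm: int = 999,
    rng: np.random.Generator | None = None,
) -> PermutationTestResult:
    """Permutation test of homogeneity of multivariate dispersions.

    Computes each point's distance to its group centroid in
    principal-coordinate space, then permutes those residual distances
    among groups and recomputes the one-way ANOVA F.
    """
    labels = np.asarray(labels)
    uniq, counts = np.unique(labels, return_counts=True)
    if uniq.size < 2:
        raise ValueError("permdisp needs at least two groups")
    if np.any(counts < 2):
        raise ValueError("dispersion undefined for groups of size 1")
    rng = rng if rng is not None else np.random.default_rng()
    z = centroid_distances(dist, labels)
    groups = _group_indices(labels)
    f_obs = _anova_f(z, groups)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        if _anova_f(z, _group_indices(perm)) >= f_obs:
            count += 1
    n, k = labels.size, uniq.size
    return PermutationTestResult(
        statistic=float(f_obs),
        p_value=(count + 1) / (n_perm + 1),
        n_permutations=n_perm,
        df_between=k - 1,
        df_within=n - k,
    )


def group_dispersion(dist: np.ndarray, labels: np.ndarray) -> dict[str, float]:
    """Mean distance-to-centroid per group (dispersion summary)."""
    labels = np.asarray(labels)
    z = centroid_distances(dist, labels)
    return {str(g): float(z[labels == g].mean()) for g in np.unique(labels)}


def broken_stick(p: int) -> np.ndarray:
    """Expected ordered proportions ``b_k = (1/p) * sum_{i=k..p} 1/i``."""
    inv = 1.0 / np.arange(1, p + 1)
    return np.cumsum(inv[::-1])[::-1] / p


def pca_broken_stick(
    table: pd.DataFrame, variable_subset: tuple[str, ...] = STARRED_COLUMNS
) -> PcaResult:
    """PCA on the correlation matrix with broken-stick significance.

    Component k is significant iff its variance proportion exceeds the
    broken-stick expectation ``b_k``.
    """
    X = table[list(variable_subset)].to_numpy(dtype=float)
    n, p = X.shape
    if p < 2 or n < 3:
        raise ValueError("need at least 2 variables and 3 rows")
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = [variable_subset[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"constant columns: {bad}")
    Z = (X - X.mean(axis=0)) / sd
    corr = np.corrcoef(Z, rowvar=False)
    vals, vecs = np.linalg.eigh(corr)
    order = np.argsort(vals)[::-1]
    vals, vecs = np.maximum(vals[order], 0.0), vecs[:, order]
    proportions = vals / vals.sum()
    bs = broken_stick(p)
    # sequential rule: leading components are significant until the first
    # one whose proportion falls at or below its broken-stick expectation
    # (trailing eigenvalues of pure noise trivially exceed the tiny
    # trailing b_k and must not be flagged)
    exceeds = proportions > bs
    significant = np.logical_and.accumulate(exceeds)
    return PcaResult(
        eigenvalues=vals,
        proportions=proportions,
        loadings=vecs,
        scores=Z @ vecs,
        broken_stick=bs,
        significant=significant,
    )
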