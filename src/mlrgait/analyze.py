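"""Cluster analysis of FOG-positive brainstem parameter pairs and
nonparametric group comparisons.

Hierarchical agglomerative clustering uses Euclidean distances and
Ward's linkage. The number of clusters is chosen from the agglomeration
coefficient (the Ward merge-height sequence): the selected k shows a
large percentage increase of the coefficient when merging below k,
followed by a plateau of the subsequent percentage changes.

Group comparisons follow the standard gatekeeping recipe: Shapiro-Wilk
normality and Levene variance-equality tests select one-way ANOVA with
t-tests, or the Kruskal-Wallis test with Mann-Whitney U post-hocs;
pairwise p-values are Bonferroni-adjusted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage

__all__ = [
    "ClusterResult",
    "StatsResult",
    "hca",
    "choose_k",
    "cluster_points",
    "compare_clusters",
]


@dataclass
class ClusterResult:
    """Linkage, agglomeration-coefficient profile and assignments."""

    points: np.ndarray  # (n, 2)
    linkage: np.ndarray  # scipy linkage matrix
    coefficients: np.ndarray  # merge height producing k clusters, k = 1..k_max
    percent_change: np.ndarray  # % increase merging k -> k-1, k = 2..k_max
    k: int
    labels: np.ndarray  # 1..k
    sizes: list[int] = field(default_factory=list)


@dataclass
class StatsResult:
    """Per-variable omnibus and pairwise comparison results."""

    variable: str
    normality_p: dict  # cluster label -> Shapiro-Wilk p
    levene_p: float
    parametric: bool
    omnibus_test: str
    omnibus_p: float
    pairwise: dict  # (label_a, label_b) -> raw p
    pairwise_adjusted: dict  # Bonferroni: min(1, p * n_comparisons)
    excluded: list = field(default_factory=list)


def hca(points: np.ndarray, k_max: int = 10) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Ward-linkage clustering and the agglomeration-coefficient profile.

    Returns ``(Z, coefficients, percent_change)`` where ``coefficients[k-1]``
    is the Ward merge height of the fusion that produces k clusters
    (k = 1..k_max) and ``percent_change[k-2]`` is the percentage increase
    of the coefficient when merging from k to k-1 clusters
    (k = 2..k_max). Merge heights are nondecreasing along the
    agglomeration sequence.
    """
    pts = np.asarray(points, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise ValueError("need at least two points")
    Z = linkage(pts, method="ward", metric="euclidean")
    n = pts.shape[0]
    k_max = min(k_max, n)
    heights = Z[:, 2]  # ascending with the agglomeration sequence
    # the merge producing k clusters is merge number n - k (1-based from the
    # end): heights[n - 1 - k] ... heights[-1] produces 1 cluster
    coeffs = np.array([heights[n - 1 - k] for k in range(1, k_max + 1)])
    pct = np.empty(k_max - 1)
    for k in range(2, k_max + 1):
        prev = coeffs[k - 1]  # coefficient at k clusters
        nxt = coeffs[k - 2]  # coefficient at k-1 clusters (larger)
        pct[k - 2] = 100.0 * (nxt - prev) / prev if prev > 0 else 0.0
    return Z, coeffs, pct


def choose_k(percent_change: np.ndarray, min_jump: float = 20.0,
             plateau_ratio: float = 0.7) -> int:
    """Cluster count from the percent-change profile of the coefficient.

    ``percent_change[k-2]`` is the increase when merging k -> k-1
    clusters. The chosen k maximizes the change among candidates whose
    subsequent changes all stay below ``plateau_ratio`` times the jump
    (the plateau). A featureless profile (max change below ``min_jump``
    %) returns k = 1 with a warning.
    """
    pct = np.asarray(percent_change, dtype=np.float64)
    if len(pct) == 0 or np.nanmax(pct) < min_jump:
        warnings.warn("featureless agglomeration profile; returning k = 1")
        return 1
    best_k, best_jump = 1, -np.inf
    for idx in range(len(pct)):
        k = idx + 2
        jump = pct[idx]
        tail = pct[idx + 1 :]
        if len(tail) and tail.max() >= plateau_ratio * jump:
            continue  # no plateau after this candidate
        if jump >= min_jump and jump > best_jump:
            best_k, best_jump = k, jump
    if best_k == 1:
        # no candidate had a clean plateau; fall back to the largest jump
        best_k = int(np.argmax(pct)) + 2
    return best_k


def cluster_points(points: np.ndarray, k: int | None = None,
                   k_max: int = 10, min_jump: float = 20.0,
                   plateau_ratio: float = 0.7) -> ClusterResult:
    """Full pipeline: Ward HCA, stopping rule (unless k given), labels."""
    pts = np.asarray(points, dtype=np.float64)
    Z, coeffs, pct = hca(pts, k_max=k_max)
    if k is None:
        k = choose_k(pct, min_jump=min_jump, plateau_ratio=plateau_ratio)
    labels = fcluster(Z, t=k, criterion="maxclust")
    sizes = [int((labels == c).sum()) for c in range(1, k + 1)]
    return ClusterResult(
        points=pts, linkage=Z, coefficients=coeffs,
        percent_change=pct, k=int(k), labels=labels, sizes=sizes,
    )


def bonferroni(p: float, n_comparisons: int) -> float:
    """Bonferroni adjustment: min(1, p * number of comparisons)."""
    return min(1.0, p * n_comparisons)


def compare_clusters(values: np.ndarray, labels: np.ndarray, variable: str = "value",
                     alpha: float = 0.05, force_nonparametric: bool | None = None
                     ) -> StatsResult:
    """Omnibus + pairwise comparison of one variable across clusters.

    Normality (Shapiro-Wilk per group) and variance equality (Levene)
    gate the parametric path (one-way ANOVA, pairwise t-tests); when
    violated, the Kruskal-Wallis test with Mann-Whitney U post-hocs is
    used. Pairwise p-values are Bonferroni-adjusted. Singleton clusters
    are excluded from testing with a warning.
    """
    values = np.asarray(values, dtype=np.float64)
    labels = np.asarray(labels)
    uniq = sorted(set(labels.tolist()))
    groups, kept, excluded = [], [], []
    for c in uniq:
        g = values[labels == c]
        if len(g) < 3:  # Shapiro needs >= 3; singletons carry no variance info
            excluded.append(c)
            warnings.warn(f"cluster {c} too small (n={len(g)}); excluded from tests")
            continue
        groups.append(g)
        kept.append(c)
    if len(groups) < 2:
        raise ValueError("need at least two clusters with n >= 3")

    normality_p = {}
    all_normal = True
    for c, g in zip(kept, groups):
        if np.ptp(g) == 0:
            p_sw = 0.0  # degenerate constant group: not plausibly normal
        else:
            p_sw = float(stats.shapiro(g).pvalue)
        normality_p[c] = p_sw
        all_normal &= p_sw > alpha
    levene_p = float(stats.levene(*groups).pvalue)
    parametric = all_normal and levene_p > alpha
    if force_nonparametric is not None:
        parametric = not force_nonparametric

    if parametric:
        omnibus_test = "anova"
        omnibus_p = float(stats.f_oneway(*groups).pvalue)
    else:
        omnibus_test = "kruskal"
        omnibus_p = float(stats.kruskal(*groups).pvalue)

    pairwise, adjusted = {}, {}
    pairs = list(combinations(range(len(groups)), 2))
    for i, j in pairs:
        if parametric:
            p = float(stats.ttest_ind(groups[i], groups[j]).pvalue)
        else:
            p = float(stats.mannwhitneyu(groups[i], groups[j], alternative="two-sided").pvalue)
        key = (kept[i], kept[j])
        pairwise[key] = p
        adjusted[key] = bonferroni(p, len(pairs))

    return StatsResult(
        variable=variable,
        normality_p=normality_p,
        levene_p=levene_p,
        parametric=parametric,
        omnibus_test=omnibus_test,
        omnibus_p=omnibus_p,
        pairwise=pairwise,
        pairwise_adjusted=adjusted,
        excluded=excluded,
    )
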