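"""Consensus k-means clustering of region profiles with CDF/silhouette model selection.

Regions are repeatedly subsampled and clustered with Euclidean k-means; the
consensus matrix records how often two regions co-cluster when co-sampled.
The empirical CDF of consensus values, its area under the curve across k,
and the silhouette of the final partition guide the choice of k: once the
relative increase in CDF area from k to k+1 drops below a threshold, extra
clusters are no longer splitting stable structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_samples

from ._frames import as_frame


@dataclass
class ConsensusResult:
    consensus: dict[int, pd.DataFrame]  # k -> region x region co-clustering frequency
    assignments: dict[int, pd.Series]  # k -> region -> cluster id (1..k)
    cdf: dict[int, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)
    area: dict[int, float] = field(default_factory=dict)
    delta_area: dict[int, float] = field(default_factory=dict)
    silhouette_mean: dict[int, float] = field(default_factory=dict)
    chosen_k: int | None = None
    k_warning: bool = False

    @property
    def assignment(self) -> pd.Series:
        if self.chosen_k is None:
            raise ValueError("no k chosen yet")
        return self.assignments[self.chosen_k]


def _region_profiles(matrix) -> pd.DataFrame:
    """Accept a RatioMatrix or a protein x region DataFrame; return regions x features."""
    return as_frame(matrix).T


def consensus_cluster(
    matrix,
    k_range: range | list[int] = range(2, 11),
    n_resamples: int = 1000,
    item_frac: float = 0.8,
    feature_frac: float = 1.0,
    n_init: int = 10,
    seed: int = 0,
    delta_threshold: float = 0.05,
) -> ConsensusResult:
    """Resampled k-means consensus clustering over a range of k.

    Each resample draws ``item_frac`` of regions (and ``feature_frac`` of
    proteins) without replacement, clusters with k-means++ (``n_init``
    restarts), and accumulates co-clustering / co-sampling counts.  The
    final per-k partition comes from average-linkage hierarchical
    clustering of ``1 - consensus``.  k is then selected via
    :func:`select_k` and the silhouette of each partition.
    """
    X = _region_profiles(matrix)
    regions = list(X.index)
    n = len(regions)
    ks = sorted(k_range)
    if min(ks) < 2 or max(ks) > n - 1:
        raise ValueError(f"k_range must lie within [2, {n - 1}]")
    m_items = max(2, int(round(item_frac * n)))
    n_feat = X.shape[1]
    m_feat = max(1, int(round(feature_frac * n_feat)))
    Xv = X.to_numpy(dtype=float)
    rng = np.random.default_rng(seed)

    result = ConsensusResult(consensus={}, assignments={})
    for k in ks:
        co = np.zeros((n, n))
        tog = np.zeros((n, n))
        done = 0
        while done < n_resamples:
            idx = rng.choice(n, size=m_items, replace=False)
            if k >= m_items:  # cannot ask for more clusters than sampled regions
                continue
            feats = (
                np.arange(n_feat)
                if m_feat == n_feat
                else rng.choice(n_feat, size=m_feat, replace=False)
            )
            km = KMeans(
                n_clusters=k,
                init="k-means++",
                n_init=n_init,
                random_state=int(rng.integers(2**31 - 1)),
            )
            labels = km.fit_predict(Xv[np.ix_(idx, feats)])
            tog[np.ix_(idx, idx)] += 1
            for c in range(k):
                mem = idx[labels == c]
                co[np.ix_(mem, mem)] += 1
            done += 1
        with np.errstate(invalid="ignore"):
            cons = np.where(tog > 0, co / np.maximum(tog, 1), 0.0)
        np.fill_diagonal(cons, 1.0)
        cons = (cons + cons.T) / 2
        cons_df = pd.DataFrame(cons, index=regions, columns=regions)
        result.consensus[k] = cons_df
        dist = 1.0 - cons
        np.fill_diagonal(dist, 0.0)
        Z = linkage(squareform(dist, checks=False), method="average")
        labels = fcluster(Z, t=k, criterion="maxclust")
        result.assignments[k] = pd.Series(labels, index=regions, name="cluster")

    cdf_and_delta_area(result)
    for k in ks:
        assign = result.assignments[k]
        if assign.nunique() >= 2:
            _, mean_sil = silhouette_scores(matrix, assign)
        else:
            mean_sil = float("nan")
        result.silhouette_mean[k] = mean_sil
    chosen, warn = select_k(result.delta_area, result.silhouette_mean, delta_threshold)
    result.chosen_k = chosen
    result.k_warning = warn
    return result


def cdf_and_delta_area(result: ConsensusResult, grid_points: int = 101) -> ConsensusResult:
    """Empirical CDF of upper-triangle consensus values, area, and delta-area.

    Delta(k) = (A(k) - A(k-1)) / A(k-1) for consecutive k; Delta at the
    smallest k is A itself.
    """
    ks = sorted(result.consensus)
    if len(ks) < 2:
        raise ValueError("need consensus matrices for at least two k values")
    grid = np.linspace(0.0, 1.0, grid_points)
    for k in ks:
        cons = result.consensus[k].to_numpy()
        iu = np.triu_indices(cons.shape[0], k=1)
        vals = cons[iu]
        F = (vals[None, :] <= grid[:, None]).mean(axis=1)
        result.cdf[k] = (grid, F)
        result.area[k] = float(np.trapezoid(F, grid))
    prev = None
    for k in ks:
        a = result.area[k]
        if prev is None:
            result.delta_area[k] = a
        elif prev > 0:
            result.delta_area[k] = (a - prev) / prev
        else:  # degenerate: previous consensus was all ones
            result.delta_area[k] = float("inf") if a > 0 else 0.0
        prev = a
    return result


def silhouette_scores(matrix, assignment: pd.Series) -> tuple[pd.Series, float]:
    """Euclidean silhouette per region and its mean; singletons score 0."""
    X = _region_profiles(matrix)
    labels = assignment.reindex(X.index)
    if labels.isna().any():
        raise ValueError("assignment missing for some regions")
    if labels.nunique() < 2:
        raise ValueError("silhouette needs at least two clusters")
    scores = silhouette_samples(X.to_numpy(dtype=float), labels.to_numpy())
    scores = np.nan_to_num(scores)  # 0/0 (identical points) -> 0 by convention
    s = pd.Series(scores, index=X.index, name="silhouette")
    return s, float(s.mean())


def select_k(
    delta_area: dict[int, float],
    silhouette_mean: dict[int, float],
    delta_threshold: float = 0.05,
) -> tuple[int, bool]:
    """Smallest k whose successor's relative area gain is below threshold.

    Requires the mean silhouette at that k to be positive.  If no k
    satisfies the rule, returns the largest k with a warning flag so the
    user can inspect the full diagnostics and override.
    """
    ks = sorted(delta_area)
    for k, k_next in zip(ks[:-1], ks[1:]):
        if delta_area[k_next] < delta_threshold and silhouette_mean.get(k, 0.0) > 0:
            return k, False
    return ks[-1], True
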