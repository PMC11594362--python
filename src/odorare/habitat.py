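"""Habitat typology by k-means with silhouette-guided model selection.

Habitat types are defined empirically: sites are clustered on subsets of
the (standardized) occupancy covariates, and the covariate subset and
cluster count K that maximize the mean silhouette coefficient define the
typology.  Cluster labels then feed the habitat-specificity entropy of the
rarity engine.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score as _sk_silhouette

__all__ = ["ClusteringResult", "kmeans_fit", "silhouette_score", "select_habitat_typology", "default_subsets"]


@dataclass
class ClusteringResult:
    covariate_subset: list[str]
    K: int
    labels: np.ndarray  # per-site cluster ids in 1..K
    silhouette: float
    centers: np.ndarray  # (K, n_covariates)

    def __post_init__(self) -> None:
        if not -1.0 <= self.silhouette <= 1.0:
            raise ValueError("silhouette out of [-1, 1]")
        if len(np.unique(self.labels)) != self.K:
            raise ValueError("empty cluster in result")


def kmeans_fit(
    X_subset: np.ndarray,
    K: int,
    seed: int = 0,
    n_init: int = 10,
    subset_names: list[str] | None = None,
) -> ClusteringResult:
    """Lloyd's k-means with seeded restarts; labels reported in 1..K."""
    X_subset = np.asarray(X_subset, dtype=float)
    if K < 2:
        raise ValueError("K must be >= 2")
    n_distinct = np.unique(X_subset, axis=0).shape[0]
    if K > n_distinct:
        raise ValueError(f"K={K} exceeds the {n_distinct} distinct rows")
    km = KMeans(n_clusters=K, n_init=n_init, random_state=seed).fit(X_subset)
    labels = km.labels_ + 1
    return ClusteringResult(
        covariate_subset=list(subset_names) if subset_names else [f"c{i}" for i in range(X_subset.shape[1])],
        K=K,
        labels=labels,
        silhouette=silhouette_score(X_subset, labels),
        centers=km.cluster_centers_,
    )


def silhouette_score(X_subset: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette (b - a) / max(a, b) with Euclidean distances.

    Points in singleton clusters contribute 0, the scikit-learn convention.
    """
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("silhouette needs at least 2 clusters")
    return float(_sk_silhouette(np.asarray(X_subset, dtype=float), labels))


def default_subsets(names: list[str], min_size: int = 2) -> list[tuple[str, ...]]:
    """All covariate subsets of size >= min_size, in deterministic order."""
    out = []
    for r in range(min_size, len(names) + 1):
        out.extend(combinations(names, r))
    return out


def select_habitat_typology(
    X: np.ndarray,
    covariate_names: list[str],
    subsets: list[tuple[str, ...]] | None = None,
    K_range: range | list[int] = range(2, 11),
    seed: int = 0,
    n_init: int = 10,
) -> ClusteringResult:
    """Exhaustive (subset, K) grid search maximizing the silhouette.

    Covariates are assumed standardized (mixed units make raw Euclidean
    distances meaningless).  Ties prefer smaller K, then shorter subsets,
    then earlier input order.
    """
    if subsets is None:
        subsets = default_subsets(covariate_names)
    if not subsets or not len(K_range):
        raise ValueError("need non-empty subsets and K_range")
    X = np.asarray(X, dtype=float)
    col = {n: i for i, n in enumerate(covariate_names)}
    seen = set()
    best: ClusteringResult | None = None
    best_key = None
    order = 0
    for sub in subsets:
        sub = tuple(sub)
        if sub in seen:
            continue
        seen.add(sub)
        Xs = X[:, [col[n] for n in sub]]
        for K in K_range:
            order += 1
            try:
                res = kmeans_fit(Xs, K, seed=seed, n_init=n_init, subset_names=list(sub))
            except ValueError:
                continue
            key = (-res.silhouette, res.K, len(sub), order)
            if best is None or key < best_key:
                best, best_key = res, key
    if best is None:
        raise ValueError("no (subset, K) combination satisfied the preconditions")
    return best
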