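"""Grouping step: K-means clustering of features and subdataset extraction.

Each active feature is represented as its vector of values across the
training samples (optionally z-scored per feature) and the features are
grouped into at most ``k`` clusters with K-means. Each cluster then defines
a two-class subdataset — the column-restriction of the training matrix to
that cluster's features — which downstream steps score and prune.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .exceptions import IdError, ParameterError
from .io import LabeledMatrix

__all__ = ["FeatureCluster", "ClusterPartition", "cluster_features",
           "build_subdataset"]


@dataclass(frozen=True)
class FeatureCluster:
    """A non-empty group of feature ids with an optional accuracy score."""

    cluster_id: int
    feature_ids: tuple[str, ...]
    score: float | None = None

    def __post_init__(self) -> None:
        if not self.feature_ids:
            raise ParameterError("a feature cluster cannot be empty")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise IdError("duplicate feature ids inside a cluster")

    def __len__(self) -> int:
        return len(self.feature_ids)


@dataclass(frozen=True)
class ClusterPartition:
    """A disjoint partition of the active feature set into clusters."""

    clusters: tuple[FeatureCluster, ...]
    iteration_index: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "clusters", tuple(self.clusters))
        if not self.clusters:
            raise ParameterError("a partition needs at least one cluster")
        all_ids = [f for c in self.clusters for f in c.feature_ids]
        if len(set(all_ids)) != len(all_ids):
            raise IdError("clusters are not disjoint")

    @property
    def feature_ids(self) -> frozenset[str]:
        return frozenset(f for c in self.clusters for f in c.feature_ids)

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)


def standardize_feature_vectors(vectors: np.ndarray) -> np.ndarray:
    """Z-score each row (feature) across samples; zero-variance rows map to 0."""
    mean = vectors.mean(axis=1, keepdims=True)
    std = vectors.std(axis=1, keepdims=True)
    safe = np.where(std == 0.0, 1.0, std)
    out = (vectors - mean) / safe
    out[np.broadcast_to(std == 0.0, out.shape)] = 0.0
    return out


def cluster_features(
    train: LabeledMatrix,
    active_features: list[str] | tuple[str, ...],
    k: int,
    seed: int,
    standardize: bool = True,
    n_init: int = 10,
    max_iter: int = 300,
) -> ClusterPartition:
    """Partition the active features into at most ``k`` clusters by K-means.

    Features are first put in canonical (original-column) order, so the
    result does not depend on the order the caller lists them in. If
    ``k >= |active_features|`` every feature becomes a singleton cluster.
    Empty clusters returned by the backend are dropped, so the effective
    cluster count can be below ``k``.
    """
    if k < 1:
        raise ParameterError(f"k must be >= 1, got {k}")
    active = tuple(active_features)
    col_idx = train.feature_index(active)  # raises IdError on unknown ids
    canonical = np.argsort(col_idx, kind="stable")
    active = tuple(active[i] for i in canonical)
    col_idx = col_idx[canonical]

    m = len(active)
    if k >= m:
        clusters = tuple(
            FeatureCluster(cluster_id=i, feature_ids=(fid,))
            for i, fid in enumerate(active)
        )
        return ClusterPartition(clusters=clusters)

    vectors = train.values[:, col_idx].T  # features as points in sample-space
    if standardize:
        vectors = standardize_feature_vectors(vectors)

    km = KMeans(n_clusters=k, init="k-means++", n_init=n_init,
                max_iter=max_iter, random_state=int(seed))
    labels = km.fit_predict(vectors)

    # relabel clusters by first occurrence so ids are order-canonical
    groups: dict[int, list[str]] = {}
    for fid, lab in zip(active, labels):
        groups.setdefault(int(lab), []).append(fid)
    ordered = sorted(groups.values(), key=lambda fids: active.index(fids[0]))
    clusters = tuple(
        FeatureCluster(cluster_id=i, feature_ids=tuple(fids))
        for i, fids in enumerate(ordered)
    )
    return ClusterPartition(clusters=clusters)


def build_subdataset(train: LabeledMatrix, cluster: FeatureCluster) -> LabeledMatrix:
    """Column-restrict ``train`` to the cluster's features (labels unchanged)."""
    return train.subset_features(cluster.feature_ids)
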