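"""Intra-cluster feature elimination (IFE).

Inside each surviving cluster a learner is fit on the cluster's subdataset
with the full training labels; its per-feature importance weights rank the
features, and the bottom ``f``% are removed — but only from clusters with
more than ``min_cluster_size`` features, so small clusters are never
emptied. This is the step that lets the engine keep shrinking the feature
pool between cluster-elimination levels.
"""

from __future__ import annotations

import math
from dataclasses import replace

from .exceptions import StateError
from .grouping import FeatureCluster, build_subdataset
from .io import LabeledMatrix
from .learners import importance_weights, make_learner

__all__ = ["feature_importances", "eliminate_within_cluster"]


def feature_importances(
    cluster: FeatureCluster,
    train: LabeledMatrix,
    learner: str = "random_forest",
    seed: int = 0,
    n_estimators: int = 100,
    importance_kind: str = "native",
) -> dict[str, float]:
    """Importance weight for every feature of the cluster.

    The learner is fit on the cluster's subdataset with the full training
    labels; weights are the forest's mean impurity decrease (or
    |coefficient| for the linear SVM), all non-negative, keyed exactly by
    the cluster's feature ids.
    """
    train.require_two_classes()
    sub = build_subdataset(train, cluster)
    model = make_learner(learner, seed, n_estimators)
    model.fit(sub.values, sub.y)
    weights = importance_weights(model, sub.values, sub.y,
                                 kind=importance_kind, seed=seed)
    return {fid: float(w) for fid, w in zip(sub.feature_ids, weights)}


def eliminate_within_cluster(
    cluster: FeatureCluster,
    importances: dict[str, float],
    f: float,
    min_cluster_size: int = 5,
) -> FeatureCluster:
    """Remove the ``f``% lowest-importance features from a cluster.

    Clusters with at most ``min_cluster_size`` features pass through
    unchanged. Otherwise ``n_remove = max(1, floor(f/100 * size))``
    features are removed, so every eligible cluster always shrinks by at
    least one feature and the reduction cannot stall; ``f = 0`` disables
    removal entirely. Importance ties at the removal boundary are broken by
    feature id: among equal weights the larger id is removed first.
    """
    if set(importances) != set(cluster.feature_ids):
        raise StateError("importance map does not cover the cluster's features")
    size = len(cluster.feature_ids)
    if f <= 0 or size <= min_cluster_size:
        return cluster
    n_remove = max(1, math.floor(f / 100.0 * size))
    n_remove = min(n_remove, size - 1)  # a cluster never becomes empty
    # lowest weight first; among ties the larger feature id goes first
    # (stable sort over an id-descending pre-order)
    removal_order = sorted(sorted(cluster.feature_ids, reverse=True),
                           key=lambda fid: importances[fid])
    doomed = set(removal_order[:n_remove])
    survivors = tuple(fid for fid in cluster.feature_ids if fid not in doomed)
    return replace(cluster, feature_ids=survivors)
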