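"""Scoring step: cluster accuracy scores and cluster elimination.

Each cluster's score is the mean held-out classification accuracy of a
learner trained on only that cluster's features, over ``t`` independent
stratified random 70/30 subsamples of the training data (Monte-Carlo
cross-validation). Clusters are then ranked by score and the lowest-scoring
ones are eliminated down to the next level of the schedule; eliminating a
cluster eliminates all of its features.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .exceptions import LabelError, ParameterError, StateError
from .grouping import ClusterPartition, FeatureCluster, build_subdataset
from .io import LabeledMatrix
from .learners import make_learner
from .preprocess import stratified_split
from .seeds import derive_seed

__all__ = ["ScoringConfig", "score_cluster", "score_partition",
           "eliminate_clusters"]


@dataclass(frozen=True)
class ScoringConfig:
    """Parameters of the repeated-subsampling cluster scorer.

    ``t`` is the number of stratified 70/30 subsamples averaged into the
    score; ``scorer_seed`` roots the per-split seed derivation.
    """

    t: int = 10
    inner_train_fraction: float = 0.7
    scorer_seed: int = 0
    learner: str = "random_forest"
    n_estimators: int = 100

    def __post_init__(self) -> None:
        if self.t < 1:
            raise ParameterError(f"t must be >= 1, got {self.t}")
        if not (0.0 < self.inner_train_fraction < 1.0):
            raise ParameterError("inner_train_fraction must be in (0, 1)")


def score_cluster(cluster: FeatureCluster, train: LabeledMatrix,
                  cfg: ScoringConfig) -> float:
    """Mean held-out accuracy of the cluster's subdataset over t subsamples."""
    train.require_two_classes()
    if train.n_pos < 2 or train.n_neg < 2:
        raise LabelError("cluster scoring needs >= 2 samples per class")
    sub = build_subdataset(train, cluster)
    accuracies = np.empty(cfg.t, dtype=np.float64)
    for i in range(cfg.t):
        split_seed = derive_seed(cfg.scorer_seed, "inner_split", i)
        pair = stratified_split(sub, cfg.inner_train_fraction, split_seed)
        model = make_learner(cfg.learner, derive_seed(cfg.scorer_seed, "fit", i),
                             cfg.n_estimators)
        model.fit(pair.train.values, pair.train.y)
        predicted = model.predict(pair.test.values)
        accuracies[i] = float(np.mean(predicted == pair.test.y))
    return float(accuracies.mean())


def score_partition(partition: ClusterPartition, train: LabeledMatrix,
                    cfg: ScoringConfig) -> ClusterPartition:
    """Score every cluster; each cluster gets its own derived scorer seed."""
    scored = []
    for cluster in partition.clusters:
        cluster_cfg = replace(
            cfg, scorer_seed=derive_seed(cfg.scorer_seed, "cluster",
                                         cluster.cluster_id))
        scored.append(replace(cluster,
                              score=score_cluster(cluster, train, cluster_cfg)))
    return replace(partition, clusters=tuple(scored))


def eliminate_clusters(partition: ClusterPartition, m_next: int) -> ClusterPartition:
    """Keep the ``m_next`` highest-scoring clusters.

    Ties at the boundary are broken deterministically: clusters are ranked
    by (score descending, cluster_id ascending), so among equal scores the
    largest cluster_id is eliminated first.
    """
    for cluster in partition.clusters:
        if cluster.score is None:
            raise StateError(f"cluster {cluster.cluster_id} is unscored")
    if not (1 <= m_next <= partition.n_clusters):
        raise ParameterError(
            f"m_next must be in [1, {partition.n_clusters}], got {m_next}")
    ranked = sorted(partition.clusters,
                    key=lambda c: (-c.score, c.cluster_id))
    keep_ids = {c.cluster_id for c in ranked[:m_next]}
    survivors = tuple(c for c in partition.clusters if c.cluster_id in keep_ids)
    return replace(partition, clusters=survivors)
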