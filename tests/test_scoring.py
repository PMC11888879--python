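"""Cluster scoring by repeated stratified subsampling, and elimination."""

from __future__ import annotations

import numpy as np
import pytest

from rceife.exceptions import ParameterError, StateError
from rceife.grouping import ClusterPartition, FeatureCluster, build_subdataset
from rceife.learners import make_learner
from rceife.preprocess import stratified_split
from rceife.scoring import ScoringConfig, eliminate_clusters, score_cluster
from rceife.seeds import derive_seed

from conftest import make_matrix


def hand_rolled_score(cluster, train, cfg):
    """Independent re-computation: materialize the t split index sets and
    average the accuracies by hand."""
    sub = build_subdataset(train, cluster)
    accs = []
    for i in range(cfg.t):
        pair = stratified_split(sub, cfg.inner_train_fraction,
                                derive_seed(cfg.scorer_seed, "inner_split", i))
        model = make_learner(cfg.learner,
                             derive_seed(cfg.scorer_seed, "fit", i),
                             cfg.n_estimators)
        model.fit(pair.train.values, pair.train.y)
        hits = sum(int(p == t) for p, t in
                   zip(model.predict(pair.test.values), pair.test.y))
        accs.append(hits / pair.test.n_samples)
    return sum(accs) / len(accs)


class TestScoreCluster:
    def test_t_one_equals_single_split_accuracy(self, balanced_matrix):
        cluster = FeatureCluster(0, balanced_matrix.feature_ids[:4])
        cfg = ScoringConfig(t=1, scorer_seed=3, n_estimators=20)
        assert score_cluster(cluster, balanced_matrix, cfg) == \
            hand_rolled_score(cluster, balanced_matrix, cfg)

    def test_separating_feature_scores_high(self):
        matrix = make_matrix(40, 40, 5, seed=21, separating=1, shift=8.0)
        # threshold-classifier oracle: the feature separates perfectly
        feature = matrix.values[:, 0]
        threshold = (feature[matrix.y].min() + feature[~matrix.y].max()) / 2
        assert ((feature > threshold) == matrix.y).all()
        cluster = FeatureCluster(0, (matrix.feature_ids[0],))
        cfg = ScoringConfig(t=10, scorer_seed=1, n_estimators=30)
        assert score_cluster(cluster, matrix, cfg) >= 0.95

    def test_pure_noise_scores_near_chance(self):
        """Chance accuracy stays inside a binomial band across seeds."""
        matrix = make_matrix(40, 40, 20, seed=22)
        cluster = FeatureCluster(0, matrix.feature_ids)
        inside = 0
        n_seeds = 40
        for seed in range(n_seeds):
            cfg = ScoringConfig(t=5, scorer_seed=seed, n_estimators=10)
            if 0.3 <= score_cluster(cluster, matrix, cfg) <= 0.7:
                inside += 1
        assert inside >= int(0.9 * n_seeds)

    def test_three_cluster_oracle_equivalence(self):
        """Exact equality with the hand-rolled recomputation, t = 10."""
        matrix = make_matrix(15, 15, 9, seed=23, separating=2)
        clusters = [FeatureCluster(i, matrix.feature_ids[3 * i:3 * i + 3])
                    for i in range(3)]
        for cluster in clusters:
            cfg = ScoringConfig(t=10, scorer_seed=100 + cluster.cluster_id,
                                n_estimators=15)
            assert score_cluster(cluster, matrix, cfg) == \
                hand_rolled_score(cluster, matrix, cfg)

    def test_signal_cluster_beats_noise_cluster(self):
        """A separating cluster rarely scores below pure noise."""
        matrix = make_matrix(25, 25, 10, seed=24, separating=3, shift=2.5)
        signal = FeatureCluster(0, matrix.feature_ids[:3])
        noise = FeatureCluster(1, matrix.feature_ids[3:])
        violations = 0
        for seed in range(25):
            cfg = ScoringConfig(t=4, scorer_seed=seed, n_estimators=10)
            if score_cluster(signal, matrix, cfg) < \
                    score_cluster(noise, matrix, cfg):
                violations += 1
        assert violations <= 2


def _scored_partition(scores):
    clusters = tuple(
        FeatureCluster(i, (f"c{i}a", f"c{i}b"), score=s)
        for i, s in enumerate(scores))
    return ClusterPartition(clusters=clusters)


class TestEliminateClusters:
    def test_top_k_selection(self):
        partition = _scored_partition([0.9, 0.8, 0.7, 0.6])
        kept = eliminate_clusters(partition, 2)
        assert [c.score for c in kept.clusters] == [0.9, 0.8]

    def test_m_next_equal_count_is_noop(self):
        partition = _scored_partition([0.5, 0.4])
        assert eliminate_clusters(partition, 2).clusters == partition.clusters

    def test_tie_rule_removes_largest_cluster_id(self):
        partition = _scored_partition([0.8, 0.8, 0.8, 0.5])
        kept = eliminate_clusters(partition, 2)
        assert [c.cluster_id for c in kept.clusters] == [0, 1]

    def test_survivor_scores_dominate_eliminated(self):
        rng = np.random.default_rng(25)
        for _ in range(50):
            scores = list(np.round(rng.random(6), 1))
            m_next = int(rng.integers(1, 7))
            partition = _scored_partition(scores)
            kept = eliminate_clusters(partition, m_next)
            assert kept.n_clusters == m_next
            kept_ids = {c.cluster_id for c in kept.clusters}
            dropped = [c for c in partition.clusters
                       if c.cluster_id not in kept_ids]
            if dropped:
                assert min(c.score for c in kept.clusters) >= \
                    max(c.score for c in dropped) - 1e-12
            # feature conservation
            assert {f for c in kept.clusters for f in c.feature_ids} | \
                {f for c in dropped for f in c.feature_ids} == \
                partition.feature_ids

    def test_unscored_cluster_is_state_error(self):
        partition = ClusterPartition(
            clusters=(FeatureCluster(0, ("a",)),))
        with pytest.raises(StateError):
            eliminate_clusters(partition, 1)

    def test_m_next_out_of_range_is_parameter_error(self):
        partition = _scored_partition([0.5, 0.4])
        with pytest.raises(ParameterError):
            eliminate_clusters(partition, 3)
        with pytest.raises(ParameterError):
            eliminate_clusters(partition, 0)


def test_scoring_config_validation():
    with pytest.raises(ParameterError):
        ScoringConfig(t=0)
    with pytest.raises(ParameterError):
        ScoringConfig(inner_train_fraction=1.0)
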