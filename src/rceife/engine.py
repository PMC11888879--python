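"""The RCE-IFE elimination loop.

One run: (optionally) undersample to balance the classes, split the samples
90/10 into an outer train/test pair, keep the 1,000 features with the
smallest two-sided t-test p-values, then walk the cluster-count schedule
``M = (M_1 > M_2 > ... > M_K)``. At each step the active features are
K-means-grouped into ``M_i`` clusters, every cluster is scored by repeated
stratified 70/30 subsampling, the ``M_i - M_{i+1}`` lowest-scoring clusters
are eliminated, each survivor loses its ``f``% least-important features
(clusters of more than five features only), and the pooled survivors are
evaluated with a freshly fitted model on the held-out test samples. The run
records one :class:`IterationResult` per level and, per feature, the number
of levels it survived.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

from .exceptions import EngineError, ParameterError
from .grouping import cluster_features
from .ife import eliminate_within_cluster, feature_importances
from .io import LabeledMatrix
from .learners import make_learner, positive_scores
from .metrics import MetricSet, auc, cohen_kappa, confusion_counts, \
    confusion_metrics
from .preprocess import stratified_split, ttest_filter, undersample
from .scoring import ScoringConfig, eliminate_clusters, score_partition
from .seeds import derive_seed

__all__ = ["Schedule", "DEFAULT_SCHEDULE", "RunConfig", "IterationResult",
           "RunResult", "run_iteration", "run_rce_ife"]

logger = logging.getLogger(__name__)

DEFAULT_SCHEDULE = (100, 90, 70, 50, 30, 20, 10, 5, 2)


@dataclass(frozen=True)
class Schedule:
    """The strictly decreasing vector of cluster counts driving elimination."""

    levels: tuple[int, ...] = DEFAULT_SCHEDULE

    def __post_init__(self) -> None:
        levels = tuple(int(m) for m in self.levels)
        object.__setattr__(self, "levels", levels)
        if len(levels) < 2:
            raise ParameterError("a schedule needs at least 2 levels")
        if levels[-1] < 1:
            raise ParameterError("the final cluster count must be >= 1")
        if any(a <= b for a, b in zip(levels, levels[1:])):
            raise ParameterError(f"schedule must be strictly decreasing: {levels}")

    def capped(self, n_features: int) -> "Schedule":
        """Cap levels at the available feature count, keeping strict decrease."""
        capped: list[int] = []
        for m in self.levels:
            m = min(m, n_features)
            if not capped or m < capped[-1]:
                capped.append(m)
        if len(capped) < 2:
            # every level collapsed onto n_features; fall back to a 2-level
            # schedule ending at the original final level
            capped = [n_features, min(self.levels[-1], max(1, n_features - 1))]
        if capped != list(self.levels):
            logger.warning("schedule %s capped to %s (%d filtered features)",
                           self.levels, tuple(capped), n_features)
        return Schedule(levels=tuple(capped))


@dataclass(frozen=True)
class RunConfig:
    """Everything one elimination run needs besides data and master seed."""

    schedule: Schedule = field(default_factory=Schedule)
    balance: bool = True
    train_fraction: float = 0.9
    n_top: int = 1000
    ttest_variant: str = "welch"
    t: int = 10
    inner_train_fraction: float = 0.7
    f: float = 10.0
    min_cluster_size_for_ife: int = 5
    learner: str = "random_forest"
    n_estimators: int = 100
    # forest size for the cluster scorer only; scoring needs a coarse
    # accuracy estimate, importance/modeling the full-size forest
    scoring_n_estimators: int | None = None
    importance_kind: str = "native"
    standardize: bool = True
    kmeans_restarts: int = 10
    kmeans_max_iter: int = 300

    def as_manifest(self) -> dict[str, object]:
        return {
            "schedule": ",".join(str(m) for m in self.schedule.levels),
            "balance": self.balance,
            "train_fraction": self.train_fraction,
            "n_top": self.n_top,
            "ttest_variant": self.ttest_variant,
            "t": self.t,
            "inner_train_fraction": self.inner_train_fraction,
            "f": self.f,
            "min_cluster_size_for_ife": self.min_cluster_size_for_ife,
            "learner": self.learner,
            "n_estimators": self.n_estimators,
            "scoring_n_estimators": (self.scoring_n_estimators
                                     if self.scoring_n_estimators is not None
                                     else self.n_estimators),
            "importance_kind": self.importance_kind,
            "standardize": self.standardize,
            "kmeans_restarts": self.kmeans_restarts,
            "kmeans_max_iter": self.kmeans_max_iter,
        }


@dataclass(frozen=True)
class IterationResult:
    """Per-level record: the survivors and their held-out performance."""

    level: int
    surviving_features: tuple[str, ...]
    metrics: MetricSet
    n_features: int


@dataclass(frozen=True)
class RunResult:
    """One full elimination run: per-level results and feature persistence."""

    per_level: tuple[IterationResult, ...]
    survival_count: dict[str, int]
    seeds: dict[str, int]

    @property
    def final(self) -> IterationResult:
        return self.per_level[-1]


def _evaluate(train: LabeledMatrix, test: LabeledMatrix, config: RunConfig,
              seed: int) -> MetricSet:
    """Fit the modeling learner on train, compute the full metric set on test."""
    model = make_learner(config.learner, seed, config.n_estimators)
    model.fit(train.values, train.y)
    y_test = test.y
    predicted = model.predict(test.values)
    counts = confusion_counts(y_test, predicted)
    base = confusion_metrics(counts)
    scores = positive_scores(model, test.values)
    return replace(base, auc=auc(scores, y_test), kappa=cohen_kappa(counts))


def run_iteration(
    train: LabeledMatrix,
    test: LabeledMatrix,
    active_features: tuple[str, ...],
    m_i: int,
    m_next: int,
    config: RunConfig,
    seed: int,
) -> tuple[IterationResult, tuple[str, ...]]:
    """One schedule step: group, score, eliminate, prune, pool, evaluate."""
    if not active_features:
        raise EngineError("no active features left")
    if not (m_i > m_next >= 1):
        raise ParameterError(f"need m_i > m_next >= 1, got {m_i} > {m_next}")

    k = min(m_i, len(active_features))
    partition = cluster_features(
        train, active_features, k, seed=derive_seed(seed, "kmeans"),
        standardize=config.standardize, n_init=config.kmeans_restarts,
        max_iter=config.kmeans_max_iter,
    )
    scoring_cfg = ScoringConfig(
        t=config.t, inner_train_fraction=config.inner_train_fraction,
        scorer_seed=derive_seed(seed, "scoring"), learner=config.learner,
        n_estimators=(config.scoring_n_estimators
                      if config.scoring_n_estimators is not None
                      else config.n_estimators),
    )
    partition = score_partition(partition, train, scoring_cfg)

    effective = partition.n_clusters
    if m_next <= effective:
        partition = eliminate_clusters(partition, m_next)
    else:
        logger.warning("only %d effective clusters at level %d; elimination skipped",
                       effective, m_next)

    pruned = []
    for cluster in partition.clusters:
        importances = feature_importances(
            cluster, train, learner=config.learner,
            seed=derive_seed(seed, "importance", cluster.cluster_id),
            n_estimators=config.n_estimators,
            importance_kind=config.importance_kind,
        )
        pruned.append(eliminate_within_cluster(
            cluster, importances, config.f, config.min_cluster_size_for_ife))
    partition = replace(partition, clusters=tuple(pruned))

    # pool survivors in original column order
    pooled = frozenset(partition.feature_ids)
    new_active = tuple(f for f in active_features if f in pooled)
    if not new_active:
        raise EngineError("intra-cluster elimination emptied the feature pool")

    train_star = train.subset_features(new_active)
    test_star = test.subset_features(new_active)
    metric_set = _evaluate(train_star, test_star, config,
                           seed=derive_seed(seed, "modeling"))
    logger.info(
        "level %d: clusters %d->%d, features %d->%d, accuracy=%s auc=%s",
        m_next, k, partition.n_clusters, len(active_features), len(new_active),
        metric_set.accuracy, metric_set.auc,
    )
    result = IterationResult(level=m_next, surviving_features=new_active,
                             metrics=metric_set, n_features=len(new_active))
    return result, new_active


def run_rce_ife(matrix: LabeledMatrix, config: RunConfig | None = None,
                seed: int = 0) -> RunResult:
    """Execute one full elimination run on a labeled matrix."""
    config = config or RunConfig()
    matrix.require_two_classes()
    seeds: dict[str, int] = {"master": int(seed)}

    if config.balance:
        seeds["undersample"] = derive_seed(seed, "undersample")
        matrix = undersample(matrix, seeds["undersample"])

    seeds["outer_split"] = derive_seed(seed, "outer_split")
    pair = stratified_split(matrix, config.train_fraction, seeds["outer_split"])
    active = tuple(ttest_filter(pair.train, n_top=config.n_top,
                                variant=config.ttest_variant))
    # restore original column order (the filter returns p-value order)
    order = {f: i for i, f in enumerate(matrix.feature_ids)}
    active = tuple(sorted(active, key=order.__getitem__))

    schedule = config.schedule.capped(len(active))
    per_level: list[IterationResult] = []
    for step, (m_i, m_next) in enumerate(zip(schedule.levels,
                                             schedule.levels[1:])):
        iter_seed = derive_seed(seed, "iteration", step)
        seeds[f"iteration_{step}"] = iter_seed
        result, active = run_iteration(pair.train, pair.test, active,
                                       m_i, m_next, config, iter_seed)
        per_level.append(result)

    survival: dict[str, int] = {f: 0 for f in matrix.feature_ids}
    for result in per_level:
        for f in result.surviving_features:
            survival[f] += 1
    return RunResult(per_level=tuple(per_level), survival_count=survival,
                     seeds=seeds)
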