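"""Repetition, averaging, survival ranking and consistency analysis.

The engine's single run is stochastic (undersampling, the outer split, the
inner scoring subsamples); results are therefore reported as the mean and
standard deviation over ``n_repeats`` independent repetitions, each with a
fresh derived seed. The survival-ranked feature list orders features by the
total number of elimination levels they persisted through, summed over
repetitions; the top-k overlap summary quantifies how consistent those
rankings are across independent aggregates.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .engine import RunConfig, RunResult, run_rce_ife
from .exceptions import ParameterError, RceIfeError
from .io import LabeledMatrix
from .metrics import METRIC_NAMES
from .seeds import derive_seed

__all__ = ["AggregateResult", "OverlapSummary", "repeat_experiment",
           "feature_survival_ranking", "topk_overlap"]


@dataclass(frozen=True)
class AggregateResult:
    """Mean +/- std of every metric per level, plus the survival ranking.

    ``per_level_stats`` maps level -> metric -> (mean, std, n_defined);
    undefined metric values are excluded from the mean and ``n_defined``
    counts the repetitions that contributed. ``ranking`` is sorted by
    survival score descending, ties by feature id ascending.
    """

    per_level_stats: dict[int, dict[str, tuple[float | None, float | None, int]]]
    ranking: tuple[tuple[str, int], ...]
    n_repeats: int
    manifest: dict[str, object]
    run_results: tuple[RunResult, ...] = ()


@dataclass(frozen=True)
class OverlapSummary:
    """Top-k agreement between rankings (the Venn-region counts for 3 sets)."""

    k: int
    common_to_all: int
    pairwise: dict[tuple[int, int], int]
    unique_counts: tuple[int, ...]


def feature_survival_ranking(
    run_results: list[RunResult] | tuple[RunResult, ...],
) -> tuple[tuple[str, int], ...]:
    """Rank features by summed survival counts across runs.

    A feature's score is the total number of recorded elimination levels it
    survived, summed over all runs; features removed at the t-test filter in
    every run score 0. Ties order by feature id ascending.
    """
    if not run_results:
        raise ParameterError("need at least one run result")
    totals: dict[str, int] = {}
    for run in run_results:
        for fid, count in run.survival_count.items():
            totals[fid] = totals.get(fid, 0) + count
    ranked = sorted(totals.items(), key=lambda item: (-item[1], item[0]))
    return tuple(ranked)


def _aggregate_levels(
    runs: tuple[RunResult, ...],
) -> dict[int, dict[str, tuple[float | None, float | None, int]]]:
    stats: dict[int, dict[str, tuple[float | None, float | None, int]]] = {}
    levels = [res.level for res in runs[0].per_level]
    extra = {"n_features"}
    for idx, level in enumerate(levels):
        per_metric: dict[str, tuple[float | None, float | None, int]] = {}
        for name in METRIC_NAMES + tuple(extra):
            values = []
            for run in runs:
                result = run.per_level[idx]
                v = (result.n_features if name == "n_features"
                     else getattr(result.metrics, name))
                if v is not None:
                    values.append(float(v))
            if values:
                arr = np.asarray(values)
                per_metric[name] = (float(arr.mean()),
                                    float(arr.std(ddof=0)), len(values))
            else:
                per_metric[name] = (None, None, 0)
        stats[level] = per_metric
    return stats


def repeat_experiment(
    matrix: LabeledMatrix,
    config: RunConfig | None = None,
    n_repeats: int = 100,
    master_seed: int = 0,
) -> AggregateResult:
    """Run the full engine ``n_repeats`` times and aggregate.

    Each repetition gets its own derived seed (fresh undersampling and outer
    split included). A failing repetition aborts with its index and seed in
    the error message.
    """
    if n_repeats < 1:
        raise ParameterError(f"n_repeats must be >= 1, got {n_repeats}")
    config = config or RunConfig()
    runs: list[RunResult] = []
    for rep in range(n_repeats):
        rep_seed = derive_seed(master_seed, "repetition", rep)
        try:
            runs.append(run_rce_ife(matrix, config, seed=rep_seed))
        except RceIfeError as exc:
            raise RceIfeError(
                f"repetition {rep} (seed {rep_seed}) failed: {exc}") from exc
    runs_t = tuple(runs)
    manifest = dict(config.as_manifest())
    manifest["master_seed"] = int(master_seed)
    manifest["repetition_seeds"] = ",".join(
        str(derive_seed(master_seed, "repetition", r)) for r in range(n_repeats))
    return AggregateResult(
        per_level_stats=_aggregate_levels(runs_t),
        ranking=feature_survival_ranking(runs_t),
        n_repeats=n_repeats,
        manifest=manifest,
        run_results=runs_t,
    )


def topk_overlap(
    rankings: list[tuple[tuple[str, int], ...]] | list[tuple],
    k: int,
) -> OverlapSummary:
    """Agreement between the top-k feature sets of several rankings.

    Returns the size of the intersection common to all rankings, each
    pairwise intersection size, and per-ranking counts of features unique
    to that ranking — for three rankings these are the Venn regions.
    """
    if k < 1:
        raise ParameterError(f"k must be >= 1, got {k}")
    if len(rankings) < 2:
        raise ParameterError("need at least two rankings to compare")
    top_sets: list[frozenset[str]] = []
    for i, ranking in enumerate(rankings):
        if len(ranking) < k:
            raise ParameterError(
                f"ranking {i} has only {len(ranking)} entries (k={k})")
        top_sets.append(frozenset(fid for fid, _ in ranking[:k]))
    common = frozenset.intersection(*top_sets)
    pairwise = {
        (i, j): len(top_sets[i] & top_sets[j])
        for i, j in combinations(range(len(top_sets)), 2)
    }
    unique = tuple(
        len(top_sets[i] - frozenset.union(*(s for j, s in enumerate(top_sets)
                                            if j != i)))
        for i in range(len(top_sets))
    )
    return OverlapSummary(k=k, common_to_all=len(common), pairwise=pairwise,
                          unique_counts=unique)
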