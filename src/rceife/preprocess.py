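"""Class balancing, the stratified outer split, and the univariate t-test filter.

These are the preparatory steps run once per repetition before the
elimination loop: random undersampling of the majority class, a stratified
train/test split of the samples (90/10 by default), and selection of the
``n_top`` features with the smallest two-sided t-test p-values on the
training side.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import SplitError, StatisticsError
from .io import LabeledMatrix

__all__ = ["SplitPair", "undersample", "stratified_split", "ttest_filter"]


@dataclass(frozen=True)
class SplitPair:
    """A disjoint train/test partition of a labeled matrix's samples."""

    train: LabeledMatrix
    test: LabeledMatrix


def undersample(matrix: LabeledMatrix, seed: int) -> LabeledMatrix:
    """Balance classes by random removal of majority-class samples.

    All minority-class samples are kept; majority-class samples are drawn
    uniformly without replacement until both counts equal the original
    minority count. Row order of the retained samples is preserved. Already
    balanced input is returned unchanged (same sample set).
    """
    matrix.require_two_classes()
    y = matrix.y
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == n_neg:
        return matrix
    minority_mask = y if n_pos < n_neg else ~y
    majority_idx = np.nonzero(~minority_mask)[0]
    n_keep = int(minority_mask.sum())
    rng = np.random.default_rng(seed)
    kept_majority = rng.choice(majority_idx, size=n_keep, replace=False)
    keep = np.sort(np.concatenate([np.nonzero(minority_mask)[0], kept_majority]))
    return matrix.subset_samples(keep)


def stratified_split(matrix: LabeledMatrix, train_fraction: float,
                     seed: int) -> SplitPair:
    """Split samples into train/test, stratified by class.

    Per class, ``floor(train_fraction * class_count)`` samples go to the
    training side and the rest to the test side; if that leaves a class with
    an empty test side, one training sample of that class is moved back, so
    both sides always contain both classes.
    """
    if not (0.0 < train_fraction < 1.0):
        raise SplitError(f"train_fraction must be in (0, 1), got {train_fraction}")
    y = matrix.y
    for cls, mask in (("pos", y), ("neg", ~y)):
        if int(mask.sum()) < 2:
            raise SplitError(f"class '{cls}' has fewer than 2 samples")

    rng = np.random.default_rng(seed)
    train_idx: list[np.ndarray] = []
    test_idx: list[np.ndarray] = []
    for mask in (y, ~y):
        members = np.nonzero(mask)[0]
        perm = rng.permutation(members)
        n_train = int(np.floor(train_fraction * len(members)))
        if n_train == len(members):  # empty-test guard
            n_train -= 1
        if n_train == 0:  # empty-train guard (low fractions)
            n_train = 1
        train_idx.append(perm[:n_train])
        test_idx.append(perm[n_train:])

    train = matrix.subset_samples(np.sort(np.concatenate(train_idx)))
    test = matrix.subset_samples(np.sort(np.concatenate(test_idx)))
    return SplitPair(train=train, test=test)


def ttest_filter(train: LabeledMatrix, n_top: int = 1000,
                 variant: str = "welch") -> list[str]:
    """Rank features by two-sided t-test p-value and keep the smallest.

    Returns ``min(n_top, q)`` feature ids ordered by ascending p-value,
    ties broken by original column order. ``variant`` selects Welch
    (default, unequal variances) or ``"pooled"`` (equal variances).
    Features constant in both classes with equal means get p = 1 so they
    sort last; constant features whose class means differ separate the
    classes perfectly and get p = 0.
    """
    if variant not in ("welch", "pooled"):
        raise StatisticsError(f"unknown t-test variant {variant!r}")
    y = train.y
    if int(y.sum()) < 2 or int((~y).sum()) < 2:
        raise StatisticsError("each class needs at least 2 samples for the t-test")

    pos, neg = train.values[y], train.values[~y]
    with np.errstate(divide="ignore", invalid="ignore"):
        result = stats.ttest_ind(pos, neg, axis=0, equal_var=(variant == "pooled"))
        pvalues = np.asarray(result.pvalue, dtype=np.float64)

    var_pos = pos.var(axis=0, ddof=1)
    var_neg = neg.var(axis=0, ddof=1)
    zero_var = (var_pos == 0.0) & (var_neg == 0.0)
    mean_equal = pos.mean(axis=0) == neg.mean(axis=0)
    pvalues[zero_var & mean_equal] = 1.0
    pvalues[zero_var & ~mean_equal] = 0.0
    pvalues[np.isnan(pvalues)] = 1.0

    order = np.argsort(pvalues, kind="stable")
    keep = order[: min(int(n_top), train.n_features)]
    return [train.feature_ids[i] for i in keep]
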