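"""Confusion-table metrics, Cohen's kappa and Mann-Whitney AUC."""

from __future__ import annotations

import numpy as np
import pytest
from sklearn.metrics import cohen_kappa_score, roc_auc_score

from rceife.exceptions import MetricError, ParameterError
from rceife.metrics import (ConfusionCounts, auc, cohen_kappa,
                            confusion_counts, confusion_metrics)


def brute_force_auc(scores, labels):
    """All-pairs concordance count, ties worth 1/2."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestConfusionMetrics:
    def test_perfect_classifier(self):
        m = confusion_metrics(ConfusionCounts(tp=5, fp=0, tn=5, fn=0))
        assert (m.accuracy, m.sensitivity, m.specificity, m.precision,
                m.f_measure) == (1.0, 1.0, 1.0, 1.0, 1.0)

    def test_all_wrong_classifier(self):
        m = confusion_metrics(ConfusionCounts(tp=0, fp=5, tn=0, fn=5))
        assert m.accuracy == 0.0
        assert m.sensitivity == 0.0
        assert m.specificity == 0.0

    def test_worked_table(self):
        m = confusion_metrics(ConfusionCounts(tp=40, fp=10, tn=45, fn=5))
        assert m.accuracy == pytest.approx(0.85)
        assert m.sensitivity == pytest.approx(0.8889, abs=5e-5)
        assert m.specificity == pytest.approx(0.8182, abs=5e-5)
        assert m.precision == pytest.approx(0.80)
        assert m.f_measure == pytest.approx(0.8421, abs=5e-5)

    def test_zero_denominator_is_undefined_not_zero(self):
        m = confusion_metrics(ConfusionCounts(tp=0, fp=0, tn=5, fn=0))
        assert m.sensitivity is None
        assert m.precision is None
        assert m.specificity == 1.0

    def test_negative_count_rejected(self):
        with pytest.raises(ParameterError):
            ConfusionCounts(tp=-1, fp=0, tn=1, fn=0)

    def test_random_tables_match_formula_oracle(self):
        """1,000 random tables against the raw formulas."""
        rng = np.random.default_rng(0)
        for _ in range(1000):
            tp, fp, tn, fn = (int(x) for x in rng.integers(0, 50, 4))
            if tp + fp + tn + fn == 0:
                continue
            m = confusion_metrics(ConfusionCounts(tp, fp, tn, fn))
            assert m.accuracy == (tp + tn) / (tp + fp + fn + tn)
            assert m.sensitivity == (tp / (tp + fn) if tp + fn else None)
            assert m.specificity == (tn / (tn + fp) if tn + fp else None)
            assert m.precision == (tp / (tp + fp) if tp + fp else None)
            assert m.f_measure == (2 * tp / (2 * tp + fp + fn)
                                   if 2 * tp + fp + fn else None)

    def test_f_measure_is_harmonic_mean(self):
        rng = np.random.default_rng(1)
        checked = 0
        for _ in range(1000):
            tp, fp, tn, fn = (int(x) for x in rng.integers(0, 30, 4))
            if tp + fp == 0 or tp + fn == 0 or tp == 0:
                continue
            m = confusion_metrics(ConfusionCounts(tp, fp, tn, fn))
            harmonic = 2 * m.precision * m.sensitivity / (m.precision +
                                                          m.sensitivity)
            assert m.f_measure == pytest.approx(harmonic)
            checked += 1
        assert checked > 500


class TestCohenKappa:
    def test_perfect_agreement(self):
        assert cohen_kappa(ConfusionCounts(tp=3, fp=0, tn=4, fn=0)) == 1.0

    def test_worked_table(self):
        assert cohen_kappa(ConfusionCounts(tp=40, fp=10, tn=45, fn=5)) == \
            pytest.approx(0.70, abs=5e-3)

    def test_chance_level_tables_near_zero(self):
        """Independent predictions with matched margins give kappa ~ 0."""
        rng = np.random.default_rng(2)
        for _ in range(100):
            truth = rng.random(1000) < 0.5
            pred = rng.random(1000) < 0.5
            kappa = cohen_kappa(confusion_counts(truth, pred))
            assert abs(kappa) < 0.1

    def test_matches_sklearn_on_random_tables(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            tp, fp, tn, fn = (int(x) for x in rng.integers(1, 30, 4))
            truth = np.array([True] * (tp + fn) + [False] * (tn + fp))
            pred = np.array([True] * tp + [False] * fn +
                            [False] * tn + [True] * fp)
            ours = cohen_kappa(ConfusionCounts(tp, fp, tn, fn))
            assert ours == pytest.approx(cohen_kappa_score(truth, pred))

    def test_degenerate_margins_undefined(self):
        assert cohen_kappa(ConfusionCounts(tp=5, fp=0, tn=0, fn=0)) is None


class TestAuc:
    def test_perfect_ranking(self):
        assert auc([0.9, 0.8, 0.7, 0.6], [True, True, False, False]) == 1.0

    def test_all_ties_is_half(self):
        assert auc([0.5] * 6, [True] * 3 + [False] * 3) == 0.5

    def test_three_of_four_pairs_concordant(self):
        assert auc([0.9, 0.4, 0.5, 0.1],
                   [True, True, False, False]) == 0.75

    def test_single_class_is_metric_error(self):
        with pytest.raises(MetricError):
            auc([0.1, 0.2], [True, True])

    def test_pos_neg_string_labels_accepted(self):
        assert auc([0.9, 0.1], np.array(["pos", "neg"])) == 1.0

    def test_matches_brute_force_and_sklearn_on_random_vectors(self):
        rng = np.random.default_rng(4)
        for _ in range(300):
            n = int(rng.integers(4, 50))
            labels = rng.random(n) < 0.5
            if labels.all() or not labels.any():
                continue
            scores = np.round(rng.random(n), 2)  # rounding forces ties
            ours = auc(scores, labels)
            assert ours == pytest.approx(brute_force_auc(scores, labels))
            assert ours == pytest.approx(roc_auc_score(labels, scores))

    def test_class_swap_reverses_auc(self):
        rng = np.random.default_rng(5)
        scores = rng.random(30)
        labels = np.array([True] * 10 + [False] * 20)
        assert auc(scores, labels) == pytest.approx(1 - auc(-scores, labels))
        assert auc(scores, labels) == pytest.approx(1 - auc(scores, ~labels))


def test_class_swap_exchanges_sensitivity_and_specificity():
    rng = np.random.default_rng(6)
    for _ in range(100):
        tp, fp, tn, fn = (int(x) for x in rng.integers(1, 30, 4))
        m = confusion_metrics(ConfusionCounts(tp, fp, tn, fn))
        swapped = confusion_metrics(ConfusionCounts(tp=tn, fp=fn, tn=tp,
                                                    fn=fp))
        assert m.sensitivity == swapped.specificity
        assert m.specificity == swapped.sensitivity
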