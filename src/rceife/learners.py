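"""Learner factory shared by the scoring, pruning and modeling steps.

Two families are supported: random forest (the default) and a
linear-kernel SVM with unit regularization (the SVM variant of the
engine). Feature importance is the forest's mean impurity decrease, or
|coefficient| for the linear SVM; an optional permutation importance is
available for the forest.
"""

from __future__ import annotations

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.svm import SVC

from .exceptions import ParameterError

__all__ = ["make_learner", "importance_weights", "positive_scores", "LEARNERS"]

LEARNERS = ("random_forest", "svm")


def make_learner(learner: str, seed: int, n_estimators: int = 100):
    if learner == "random_forest":
        return RandomForestClassifier(n_estimators=int(n_estimators),
                                      random_state=int(seed), n_jobs=1)
    if learner == "svm":
        return SVC(kernel="linear", C=1.0, random_state=int(seed))
    raise ParameterError(f"unknown learner {learner!r}; expected one of {LEARNERS}")


def importance_weights(model, X: np.ndarray, y: np.ndarray,
                       kind: str = "native", seed: int = 0) -> np.ndarray:
    """Non-negative per-feature importance weights from a fitted model."""
    if kind == "permutation":
        result = permutation_importance(model, X, y, n_repeats=10,
                                        random_state=int(seed))
        return np.clip(result.importances_mean, 0.0, None)
    if kind != "native":
        raise ParameterError(f"unknown importance kind {kind!r}")
    if hasattr(model, "feature_importances_"):
        return np.asarray(model.feature_importances_, dtype=np.float64)
    if hasattr(model, "coef_"):
        return np.abs(np.asarray(model.coef_, dtype=np.float64)).ravel()
    raise ParameterError(f"model {type(model).__name__} exposes no importance")


def positive_scores(model, X: np.ndarray) -> np.ndarray:
    """Continuous score for the positive class (probability or margin)."""
    if hasattr(model, "predict_proba"):
        classes = list(model.classes_)
        return model.predict_proba(X)[:, classes.index(True)]
    margins = model.decision_function(X)
    # decision_function is oriented toward classes_[1]
    return margins if model.classes_[1] else -margins
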