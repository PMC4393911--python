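"""Pluggable classifiers and the SVC-with-RBF protocol.

The reference protocol is a support vector classifier with an RBF kernel
whose cost ``C = 2**c`` and kernel width ``gamma = 2**g`` are tuned on a
base-2 logarithmic grid — c in [-5, 15], g in [3, -15], step 2 — by
stratified ten-fold cross-validation.  Back-propagation network (BPNN) and
Gaussian Naive Bayes adapters share the same fit/predict contract so the
selector and the evaluation protocol can swap them in.

Feature tables are pandas DataFrames: numeric feature columns plus a final
``label`` column.  Inputs are z-score standardized inside the model
pipeline (statistics learned on the training folds only).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.naive_bayes import GaussianNB
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

logger = logging.getLogger(__name__)

__all__ = [
    "ClassifierSpec",
    "TrainedClassifier",
    "split_xy",
    "majority_proportion",
    "stratified_fold_indices",
    "grid_search_svc",
    "cross_val_accuracy",
    "fit",
    "predict",
]

FAMILIES = ("svc_rbf", "bpnn", "naive_bayes")
C_EXPONENT_LIMITS = (-5, 15)
G_EXPONENT_LIMITS = (-15, 3)


@dataclass(frozen=True)
class ClassifierSpec:
    """Configuration of one classifier family.

    ``c_exponents`` / ``g_exponents`` are inclusive base-2 exponent ranges
    walked with step 2 (the conventional libsvm coarse grid); they apply
    to the svc_rbf family only.  ``hyperparams`` freezes ``(C, gamma)``
    and skips the grid (used by the selector, which tunes once per round).
    """

    family: str = "svc_rbf"
    c_exponents: tuple[int, int] = (-5, 15)
    g_exponents: tuple[int, int] = (3, -15)
    cv_folds: int = 10
    seed: int = 0
    hyperparams: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; "
                             f"choose from {FAMILIES}")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        lo_c, hi_c = sorted(self.c_exponents)
        if lo_c < C_EXPONENT_LIMITS[0] or hi_c > C_EXPONENT_LIMITS[1]:
            raise ValueError(f"c exponents must lie in {C_EXPONENT_LIMITS}")
        lo_g, hi_g = sorted(self.g_exponents)
        if lo_g < G_EXPONENT_LIMITS[0] or hi_g > G_EXPONENT_LIMITS[1]:
            raise ValueError(f"g exponents must lie in {G_EXPONENT_LIMITS}")

    def c_grid(self) -> list[float]:
        lo, hi = sorted(self.c_exponents)
        return [2.0 ** e for e in range(lo, hi + 1, 2)]

    def g_grid(self) -> list[float]:
        lo, hi = sorted(self.g_exponents)
        return [2.0 ** e for e in range(lo, hi + 1, 2)]


@dataclass
class TrainedClassifier:
    """A fitted pipeline bound to the feature names it was trained on."""

    pipeline: Pipeline
    features: tuple[str, ...]
    spec: ClassifierSpec
    hyperparams: tuple[float, float] | None = None
    classes: tuple = field(default_factory=tuple)


def split_xy(table: pd.DataFrame,
             feature_subset: Sequence[str] | None = None,
             ) -> tuple[np.ndarray, np.ndarray, tuple[str, ...]]:
    """Split a feature table into (X, y, feature_names)."""
    if "label" not in table.columns:
        raise ValueError("feature table must carry a 'label' column")
    features = tuple(c for c in table.columns if c != "label") \
        if feature_subset is None else tuple(feature_subset)
    missing = [f for f in features if f not in table.columns]
    if missing:
        raise KeyError(f"features missing from table: {missing}")
    X = table.loc[:, list(features)].to_numpy(dtype=float)
    y = table["label"].to_numpy()
    return X, y, features


def majority_proportion(y: np.ndarray) -> float:
    _, counts = np.unique(y, return_counts=True)
    return float(counts.max() / counts.sum())


def _make_estimator(spec: ClassifierSpec,
                    C: float = 1.0, gamma: float | str = "scale") -> Pipeline:
    if spec.family == "svc_rbf":
        clf = SVC(kernel="rbf", C=C, gamma=gamma)
    elif spec.family == "bpnn":
        clf = MLPClassifier(hidden_layer_sizes=(10,), max_iter=1000,
                            random_state=spec.seed)
    else:
        clf = GaussianNB()
    return Pipeline([("scale", StandardScaler()), ("clf", clf)])


def stratified_fold_indices(y: np.ndarray, folds: int, seed: int,
                            ) -> list[np.ndarray]:
    """Seeded stratified fold assignment; folds are reduced (to the
    smallest class count, floor 2) with a logged warning when a class is
    rarer than the requested fold count."""
    from sklearn.model_selection import KFold, StratifiedKFold

    _, counts = np.unique(y, return_counts=True)
    min_class = int(counts.min())
    effective = folds
    if min_class < folds:
        effective = max(2, min_class)
        logger.warning(
            "reducing CV folds from %d to %d (smallest class has %d "
            "samples)", folds, effective, min_class)
    if min_class >= 2:
        splitter = StratifiedKFold(n_splits=effective, shuffle=True,
                                   random_state=seed)
    else:
        splitter = KFold(n_splits=effective, shuffle=True, random_state=seed)
    return [test for _, test in splitter.split(np.zeros_like(y), y)]


def _pooled_cv_accuracy(X: np.ndarray, y: np.ndarray,
                        estimator_factory,
                        fold_indices: list[np.ndarray]) -> float:
    """Accuracy pooled over held-out folds (micro-average)."""
    n = len(y)
    correct = 0
    all_idx = np.arange(n)
    for test_idx in fold_indices:
        train_mask = np.ones(n, dtype=bool)
        train_mask[test_idx] = False
        train_idx = all_idx[train_mask]
        if len(np.unique(y[train_idx])) < 2:
            # degenerate fold: score as majority vote
            maj = pd.Series(y[train_idx]).mode().iloc[0]
            correct += int(np.sum(y[test_idx] == maj))
            continue
        est = estimator_factory()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est.fit(X[train_idx], y[train_idx])
            pred = est.predict(X[test_idx])
        correct += int(np.sum(pred == y[test_idx]))
    return correct / n


def grid_search_svc(X: np.ndarray, y: np.ndarray, spec: ClassifierSpec,
                    fold_indices: list[np.ndarray] | None = None,
                    ) -> tuple[float, float, float]:
    """Pick (C, gamma) maximizing pooled CV accuracy on the base-2 grid.

    Ties break toward smaller C, then smaller gamma (smoother models);
    the walk order makes that the first strict improvement rule.
    Returns ``(C, gamma, best_accuracy)``.
    """
    if fold_indices is None:
        fold_indices = stratified_fold_indices(y, spec.cv_folds, spec.seed)
    best = (None, None, -1.0)
    for C in spec.c_grid():
        for gamma in spec.g_grid():
            acc = _pooled_cv_accuracy(
                X, y, lambda C=C, g=gamma: _make_estimator(spec, C, g),
                fold_indices)
            if acc > best[2]:
                best = (C, gamma, acc)
    return best


def cross_val_accuracy(table: pd.DataFrame,
                       feature_subset: Sequence[str] | None = None,
                       spec: ClassifierSpec = ClassifierSpec(),
                       fold_indices: list[np.ndarray] | None = None,
                       ) -> float:
    """Stratified k-fold accuracy for a feature subset.

    Rows are first put in a canonical order (sorted by index) so the
    result is invariant to row permutation under the same seed.  For
    svc_rbf without frozen hyperparameters, (C, gamma) are chosen by grid
    search over the same folds and the best grid accuracy is returned —
    the classical libsvm tuning protocol.  ``fold_indices`` (positions
    into the canonically sorted table) lets a caller hold the fold
    assignment fixed across many subset evaluations.
    """
    if feature_subset is not None and len(feature_subset) == 0:
        raise ValueError("empty feature subset")
    table = table.sort_index(kind="stable")
    X, y, _ = split_xy(table, feature_subset)
    if fold_indices is None:
        fold_indices = stratified_fold_indices(y, spec.cv_folds, spec.seed)
    if len(y) < len(fold_indices):
        raise ValueError("fewer samples than folds")
    if spec.family == "svc_rbf" and spec.hyperparams is None:
        _, _, acc = grid_search_svc(X, y, spec, fold_indices)
        return acc
    if spec.family == "svc_rbf":
        C, gamma = spec.hyperparams
        factory = lambda: _make_estimator(spec, C, gamma)  # noqa: E731
    else:
        factory = lambda: _make_estimator(spec)  # noqa: E731
    return _pooled_cv_accuracy(X, y, factory, fold_indices)


def fit(table: pd.DataFrame,
        feature_subset: Sequence[str] | None = None,
        spec: ClassifierSpec = ClassifierSpec()) -> TrainedClassifier:
    """Fit on the full table; svc_rbf tunes (C, gamma) by CV first
    unless the spec freezes them."""
    X, y, features = split_xy(table, feature_subset)
    hyper = spec.hyperparams
    if spec.family == "svc_rbf":
        if hyper is None:
            C, gamma, _ = grid_search_svc(X, y, spec)
            hyper = (C, gamma)
        est = _make_estimator(spec, *hyper)
    else:
        est = _make_estimator(spec)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        est.fit(X, y)
    return TrainedClassifier(pipeline=est, features=features, spec=spec,
                             hyperparams=hyper,
                             classes=tuple(est.named_steps["clf"].classes_))


def predict(clf: TrainedClassifier, table: pd.DataFrame) -> np.ndarray:
    """Predict labels, aligning columns by name to the training features."""
    missing = [f for f in clf.features if f not in table.columns]
    if missing:
        raise KeyError(f"prediction table lacks training features {missing}")
    X = table.loc[:, list(clf.features)].to_numpy(dtype=float)
    return clf.pipeline.predict(X)
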