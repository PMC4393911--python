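"""The Binary Matrix Shuffling Filter (BMSF).

BMSF is a wrapper feature selector.  One round, over the m currently
surviving features, proceeds as:

1.  Draw a balanced random k x m inclusion matrix over {0, 1}: each column
    is an independent uniform permutation of k/2 ones and k/2 zeros, so
    every feature is included in exactly half the combinations (k = 50 by
    default).
2.  Score every row: cross-validated classification accuracy of the
    classifier trained on just the features with a 1 in that row, with the
    fold assignment held fixed across rows so rows differ only by feature
    content.
3.  Fit a surrogate regression (support vector regression, RBF kernel)
    mapping inclusion vectors to accuracy.
4.  For each feature j, force column j to all-ones (predictions Z1) and
    to all-zeros (predictions Z0).  The margin mean(Z1) - mean(Z0)
    estimates the feature's contribution in the context of random
    feature combinations, interactions included.
5.  Keep features with positive margin, drop the rest; repeat with fresh
    per-round seeds until a round drops nothing.

The procedure returns a parsimonious subset ranked by final-round margin.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Protocol, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from bmsf.classifiers import (
    ClassifierSpec,
    _make_estimator,
    _pooled_cv_accuracy,
    grid_search_svc,
    majority_proportion,
    split_xy,
    stratified_fold_indices,
)

__all__ = [
    "BinaryDesignMatrix",
    "BMSFParams",
    "FlipScores",
    "MetaModel",
    "RoundRecord",
    "SelectionResult",
    "generate_binary_matrix",
    "evaluate_combinations",
    "fit_meta_model",
    "flip_scores",
    "bmsf_round",
    "bmsf_select",
]


@dataclass(frozen=True)
class BinaryDesignMatrix:
    """Balanced k x m 0/1 inclusion matrix; every column sums to k/2."""

    entries: np.ndarray
    column_order: tuple[str, ...]

    def __post_init__(self) -> None:
        k, m = self.entries.shape
        if m != len(self.column_order):
            raise ValueError("column_order length must match matrix width")
        sums = self.entries.sum(axis=0)
        if k % 2 or not np.all(sums == k // 2):
            raise ValueError("each column must contain exactly k/2 ones")

    @property
    def k(self) -> int:
        return self.entries.shape[0]

    @property
    def m(self) -> int:
        return self.entries.shape[1]


@dataclass(frozen=True)
class BMSFParams:
    """Tunables of the selector.

    ``k`` is the number of random feature combinations per round (even,
    default 50); the classifier spec supplies the CV protocol used to
    score each combination.  ``min_features``/``max_rounds`` are
    safeguards, not targets.
    """

    k: int = 50
    cv_folds: int = 10
    classifier: ClassifierSpec = field(
        default_factory=lambda: ClassifierSpec(cv_folds=10))
    max_rounds: int = 20
    min_features: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k % 2 or self.k < 4:
            raise ValueError("k must be even and >= 4")
        if self.max_rounds < 1:
            raise ValueError("max_rounds must be >= 1")
        if self.min_features < 1:
            raise ValueError("min_features must be >= 1")


class PredictsAccuracy(Protocol):
    """Anything mapping a (rows x m) 0/1 matrix to predicted accuracy."""

    def predict(self, X: np.ndarray) -> np.ndarray: ...


@dataclass
class MetaModel:
    """Surrogate from inclusion vectors to CV accuracy.

    ``is_constant`` flags a degenerate fit (the observed accuracies had
    no spread), so a caller can stop the elimination loop.
    """

    model: PredictsAccuracy | None
    constant: float | None = None

    @property
    def is_constant(self) -> bool:
        return self.model is None

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.model is None:
            return np.full(X.shape[0], self.constant)
        return np.asarray(self.model.predict(X), dtype=float)


@dataclass(frozen=True)
class FlipScores:
    """Column-forcing contrasts: per feature, the surrogate's mean
    prediction with the feature forced in (Z1) vs forced out (Z0)."""

    features: tuple[str, ...]
    mean_z1: np.ndarray
    mean_z0: np.ndarray

    @property
    def margin(self) -> np.ndarray:
        return self.mean_z1 - self.mean_z0

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "feature": self.features,
            "mean_z1": self.mean_z1,
            "mean_z0": self.mean_z0,
            "margin": self.margin,
        })


@dataclass(frozen=True)
class RoundRecord:
    features_in: tuple[str, ...]
    scores: FlipScores
    dropped: tuple[str, ...]
    hyperparams: tuple[float, float] | None
    meta_constant: bool = False


@dataclass
class SelectionResult:
    """Outcome of multi-round BMSF screening."""

    selected: tuple[str, ...]
    rounds: tuple[RoundRecord, ...]
    params: BMSFParams
    status: str  # "converged" | "min_features" | "max_rounds"

    def to_dict(self) -> dict:
        return {
            "selected": list(self.selected),
            "status": self.status,
            "n_rounds": len(self.rounds),
            "rounds": [
                {
                    "features_in": list(r.features_in),
                    "dropped": list(r.dropped),
                    "margins": dict(zip(r.scores.features,
                                        map(float, r.scores.margin))),
                    "hyperparams": list(r.hyperparams)
                    if r.hyperparams else None,
                }
                for r in self.rounds
            ],
            "params": {
                "k": self.params.k,
                "cv_folds": self.params.cv_folds,
                "max_rounds": self.params.max_rounds,
                "min_features": self.params.min_features,
                "seed": self.params.seed,
                "classifier_family": self.params.classifier.family,
            },
        }


# ---------------------------------------------------------------------------


def generate_binary_matrix(m: int, k: int, seed: int,
                           feature_names: Sequence[str] | None = None,
                           ) -> BinaryDesignMatrix:
    """Draw the balanced random inclusion matrix.

    Each column is an independent uniform random permutation of k/2 ones
    and k/2 zeros; reproducible from ``seed``.
    """
    if k % 2:
        raise ValueError("k must be even to balance columns")
    if m < 1:
        raise ValueError("m must be >= 1")
    rng = np.random.default_rng(seed)
    base = np.repeat(np.array([1, 0], dtype=np.int8), k // 2)
    cols = [rng.permutation(base) for _ in range(m)]
    names = tuple(feature_names) if feature_names is not None \
        else tuple(f"f{j}" for j in range(m))
    return BinaryDesignMatrix(entries=np.column_stack(cols),
                              column_order=names)


def evaluate_combinations(table: pd.DataFrame,
                          design: BinaryDesignMatrix,
                          params: BMSFParams,
                          fold_seed: int | None = None) -> np.ndarray:
    """CV accuracy of every design-matrix row's feature combination.

    The stratified fold assignment is computed once (from ``fold_seed``,
    default ``params.seed``) and reused for every row, so rows differ
    only by feature content.  Rows with zero active features are scored
    at the majority-class proportion.
    """
    table = table.sort_index(kind="stable")
    X, y, _ = split_xy(table, design.column_order)
    if len(y) < params.cv_folds:
        raise ValueError("fewer samples than CV folds")
    seed = params.seed if fold_seed is None else fold_seed
    folds = stratified_fold_indices(y, params.cv_folds, seed)
    spec = params.classifier
    maj = majority_proportion(y)
    acc = np.empty(design.k, dtype=float)
    for i, row in enumerate(design.entries):
        active = np.flatnonzero(row)
        if active.size == 0:
            acc[i] = maj
            continue
        Xs = X[:, active]
        if spec.family == "svc_rbf" and spec.hyperparams is None:
            _, _, acc[i] = grid_search_svc(Xs, y, spec, folds)
        elif spec.family == "svc_rbf":
            C, gamma = spec.hyperparams
            acc[i] = _pooled_cv_accuracy(
                Xs, y, lambda: _make_estimator(spec, C, gamma), folds)
        else:
            acc[i] = _pooled_cv_accuracy(
                Xs, y, lambda: _make_estimator(spec), folds)
    return acc


def fit_meta_model(design: BinaryDesignMatrix, acc: np.ndarray,
                   params: BMSFParams, seed: int | None = None) -> MetaModel:
    """Fit the SVR surrogate mapping inclusion vectors to accuracy.

    C and gamma are tuned by 5-fold CV on the k meta-samples over the
    same base-2 exponent grid as the classifier; epsilon is 0.01 because
    accuracies live in a narrow band.  A spread-less accuracy vector
    yields a flagged constant surrogate.
    """
    acc = np.asarray(acc, dtype=float)
    if len(acc) != design.k:
        raise ValueError("accuracy vector length must equal design.k")
    if float(np.ptp(acc)) < 1e-9:
        return MetaModel(model=None, constant=float(acc[0]))
    X = design.entries.astype(float)
    seed = params.seed if seed is None else seed
    spec = params.classifier
    n_splits = min(5, design.k)
    cv = KFold(n_splits=n_splits, shuffle=True, random_state=seed)
    splits = list(cv.split(X))
    best = (1.0, 0.1, np.inf)
    for C in spec.c_grid():
        for gamma in spec.g_grid():
            sse = 0.0
            for train_idx, test_idx in splits:
                svr = Pipeline([
                    ("scale", StandardScaler()),
                    ("svr", SVR(kernel="rbf", C=C, gamma=gamma,
                                epsilon=0.01)),
                ])
                svr.fit(X[train_idx], acc[train_idx])
                resid = svr.predict(X[test_idx]) - acc[test_idx]
                sse += float(resid @ resid)
            if sse < best[2]:
                best = (C, gamma, sse)
    final = Pipeline([
        ("scale", StandardScaler()),
        ("svr", SVR(kernel="rbf", C=best[0], gamma=best[1], epsilon=0.01)),
    ])
    final.fit(X, acc)
    return MetaModel(model=final)


def flip_scores(meta: PredictsAccuracy,
                design: BinaryDesignMatrix) -> FlipScores:
    """Column-forcing contrast for every feature.

    For feature j, build test set T1 = design with column j forced to
    all ones and T0 = forced to all zeros, predict both with the
    surrogate, and record the two means.  ``meta`` is anything with a
    ``predict`` method, so analytic surrogates can be injected.
    """
    base = design.entries.astype(float)
    mean_z1 = np.empty(design.m)
    mean_z0 = np.empty(design.m)
    for j in range(design.m):
        t1 = base.copy()
        t1[:, j] = 1.0
        t0 = base.copy()
        t0[:, j] = 0.0
        mean_z1[j] = float(np.mean(meta.predict(t1)))
        mean_z0[j] = float(np.mean(meta.predict(t0)))
    return FlipScores(features=design.column_order,
                      mean_z1=mean_z1, mean_z0=mean_z0)


def _round_seeds(round_seed: int) -> tuple[int, int, int]:
    ss = np.random.SeedSequence(round_seed)
    a, b, c = (int(s) % (2 ** 31) for s in ss.generate_state(3))
    return a, b, c


def bmsf_round(table: pd.DataFrame,
               current_features: Sequence[str],
               params: BMSFParams,
               round_seed: int,
               ) -> tuple[tuple[str, ...], RoundRecord]:
    """One screening round over the current feature set.

    For svc_rbf the hyperparameters are grid-searched once on the full
    current set and frozen for all k row evaluations.  Features with
    margin > 0 are kept; if none would survive, the single best-margin
    feature is retained (ties to earlier feature order).
    """
    current = tuple(current_features)
    if not current:
        raise ValueError("current feature set is empty")
    design_seed, fold_seed, meta_seed = _round_seeds(round_seed)

    spec = params.classifier
    hyper = spec.hyperparams
    if spec.family == "svc_rbf" and hyper is None:
        sorted_table = table.sort_index(kind="stable")
        X, y, _ = split_xy(sorted_table, current)
        folds = stratified_fold_indices(y, params.cv_folds, fold_seed)
        C, gamma, _ = grid_search_svc(X, y, spec, folds)
        hyper = (C, gamma)
    round_params = replace(params,
                           classifier=replace(spec, hyperparams=hyper))

    design = generate_binary_matrix(len(current), params.k, design_seed,
                                    feature_names=current)
    acc = evaluate_combinations(table, design, round_params, fold_seed)
    meta = fit_meta_model(design, acc, round_params, meta_seed)
    scores = flip_scores(meta, design)

    if meta.is_constant:
        record = RoundRecord(features_in=current, scores=scores,
                             dropped=(), hyperparams=hyper,
                             meta_constant=True)
        return current, record

    margin = scores.margin
    keep_mask = margin > 0
    if not keep_mask.any():
        keep_mask[int(np.argmax(margin))] = True
    kept = tuple(f for f, keep in zip(current, keep_mask) if keep)
    dropped = tuple(f for f, keep in zip(current, keep_mask) if not keep)
    record = RoundRecord(features_in=current, scores=scores,
                         dropped=dropped, hyperparams=hyper)
    return kept, record


def bmsf_select(table: pd.DataFrame,
                params: BMSFParams = BMSFParams(),
                feature_subset: Sequence[str] | None = None,
                ) -> SelectionResult:
    """Multi-round BMSF screening to a parsimonious subset.

    Rounds run with fresh deterministically derived seeds until one drops
    nothing (or a flagged constant surrogate stops the loop), the set
    reaches ``min_features``, or ``max_rounds`` is hit.  The surviving
    features are ranked by final-round margin, descending.
    """
    _, _, features = split_xy(table, feature_subset)
    if len(features) < 2:
        raise ValueError("need at least 2 candidate features")
    labels = table["label"].to_numpy()
    if len(np.unique(labels)) < 2:
        raise ValueError("need at least 2 classes")

    current = features
    rounds: list[RoundRecord] = []
    status = "max_rounds"
    for r in range(params.max_rounds):
        round_seed = int(np.random.SeedSequence(
            (params.seed, r)).generate_state(1)[0] % (2 ** 31))
        kept, record = bmsf_round(table, current, params, round_seed)
        rounds.append(record)
        if record.meta_constant or not record.dropped:
            current = kept
            status = "converged"
            break
        current = kept
        if len(current) <= params.min_features:
            status = "min_features"
            break

    last = rounds[-1]
    margin_of = dict(zip(last.scores.features, last.scores.margin))
    ordered = tuple(sorted(
        current, key=lambda f: (-margin_of.get(f, 0.0), current.index(f))))
    return SelectionResult(selected=ordered, rounds=tuple(rounds),
                           params=params, status=status)
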