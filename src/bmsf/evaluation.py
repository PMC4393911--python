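"""Replicated evaluation protocol: stratified 2:1 splits, accuracy,
Matthews correlation coefficient and recall.

The protocol mirrors a replicated hold-out design on severely imbalanced
classes: each replication splits every class 2:1 into train and test,
feature selection runs on the training rows only, a classifier is fitted
on the selected features and scored on the held-out third, and results
are summarized as mean +/- sample standard deviation over replications.

Per-class train counts come from an exact-global-2:1 largest-remainder
allocation: each class contributes floor(n_c * 2/3) training rows and the
remaining slots (up to round(N * 2/3) in total) go to the classes with the
largest fractional remainders, ties broken by class name.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from fractions import Fraction
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from bmsf.classifiers import ClassifierSpec, fit, predict

__all__ = [
    "SplitSpec",
    "ConfusionCounts",
    "EvaluationReport",
    "ExperimentSummary",
    "class_train_counts",
    "stratified_split",
    "confusion_counts",
    "binary_metrics",
    "multiclass_report",
    "replicate_experiment",
]

Selector = Callable[[pd.DataFrame, int], Sequence[str]]


@dataclass(frozen=True)
class SplitSpec:
    """Stratified train/test split protocol."""

    train_fraction: float = 2.0 / 3.0
    n_replications: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.n_replications < 1:
            raise ValueError("n_replications must be >= 1")


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion-matrix counts."""

    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass
class EvaluationReport:
    """Per-replication test-set report."""

    accuracy: float
    recall: dict[str, float]
    confusion: pd.DataFrame
    replication_index: int = 0
    mcc: float | None = None
    selected_features: tuple[str, ...] = ()


@dataclass
class ExperimentSummary:
    """Replicated-experiment summary in 'mean +/- SD' form."""

    reports: list[EvaluationReport]
    accuracy_mean: float
    accuracy_sd: float
    recall_mean: dict[str, float]
    recall_sd: dict[str, float]

    def format_accuracy(self) -> str:
        return f"{100 * self.accuracy_mean:.2f} ± " \
               f"{100 * self.accuracy_sd:.2f}"


def class_train_counts(class_sizes: dict[str, int],
                       train_fraction: float = 2.0 / 3.0) -> dict[str, int]:
    """Largest-remainder training-count allocation, exact in total.

    Each class gets floor(n_c * f); the remaining train slots (total
    target = round-half-up(N * f)) go to the classes with the largest
    fractional remainders, ties broken by class name.  Singleton classes
    are forced entirely into train with a warning.
    """
    singletons = {c for c, n in class_sizes.items() if n == 1}
    if singletons:
        warnings.warn(
            f"classes with a single sample go to train: {sorted(singletons)}")
    rest = {c: n for c, n in class_sizes.items() if c not in singletons}
    total = sum(rest.values())
    # exact rational arithmetic so equal fractional remainders tie
    # exactly (2/3 is not a float)
    frac = Fraction(train_fraction).limit_denominator(10 ** 6)
    target = int(math.floor(frac * total + Fraction(1, 2)))
    base = {c: int(math.floor(n * frac)) for c, n in rest.items()}
    remainder = {c: n * frac - base[c] for c, n in rest.items()}
    leftover = target - sum(base.values())
    order = sorted(rest, key=lambda c: (-remainder[c], c))
    for c in order[:leftover]:
        base[c] += 1
    for c in singletons:
        base[c] = 1
    return base


def stratified_split(table: pd.DataFrame, spec: SplitSpec,
                     replication_index: int = 0,
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One stratified 2:1 split; replications use independent per-class
    shuffles derived from ``(seed, replication_index)``."""
    if table.empty:
        raise ValueError("empty table")
    labels = table["label"]
    sizes = labels.value_counts().to_dict()
    n_train = class_train_counts({str(k): int(v) for k, v in sizes.items()},
                                 spec.train_fraction)
    ss = np.random.SeedSequence((spec.seed, replication_index))
    classes = sorted(map(str, sizes))
    children = ss.spawn(len(classes))
    train_idx: list = []
    test_idx: list = []
    for cls, child in zip(classes, children):
        rng = np.random.default_rng(child)
        idx = table.index[labels.astype(str) == cls].to_numpy()
        perm = rng.permutation(len(idx))
        k = n_train[cls]
        train_idx.extend(idx[perm[:k]])
        test_idx.extend(idx[perm[k:]])
    return table.loc[train_idx], table.loc[test_idx]


def confusion_counts(y_true: np.ndarray, y_pred: np.ndarray,
                     positive) -> ConfusionCounts:
    """Collapse label vectors to binary counts for a positive class."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors must have the same length")
    t = y_true == positive
    p = y_pred == positive
    return ConfusionCounts(
        TP=int(np.sum(t & p)), TN=int(np.sum(~t & ~p)),
        FP=int(np.sum(~t & p)), FN=int(np.sum(t & ~p)))


def binary_metrics(counts: ConfusionCounts) -> dict[str, float]:
    """Accuracy, MCC and recall from binary confusion counts.

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)), defined
    as 0 when any factor of the denominator vanishes; recall is 0 when
    the positive class is absent.
    """
    tp, tn, fp, fn = counts.TP, counts.TN, counts.FP, counts.FN
    total = counts.total
    if total == 0:
        raise ValueError("empty confusion matrix")
    accuracy = (tp + tn) / total
    denom = ((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = 0.0 if denom == 0 else (tp * tn - fp * fn) / math.sqrt(denom)
    recall = 0.0 if tp + fn == 0 else tp / (tp + fn)
    return {"accuracy": accuracy, "MCC": mcc, "recall": recall}


def multiclass_report(y_true: np.ndarray, y_pred: np.ndarray,
                      replication_index: int = 0) -> EvaluationReport:
    """Overall accuracy plus one-vs-rest recall (sensitivity) per class,
    with the full confusion matrix retained."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors must have the same length")
    classes = sorted(map(str, set(y_true.astype(str)) |
                         set(y_pred.astype(str))))
    conf = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    for t, p in zip(y_true.astype(str), y_pred.astype(str)):
        conf.loc[t, p] += 1
    accuracy = float(np.trace(conf.to_numpy()) / len(y_true))
    recall = {}
    for cls in classes:
        row = int(conf.loc[cls].sum())
        recall[cls] = float(conf.loc[cls, cls] / row) if row else 0.0
    mcc = None
    if len(classes) == 2:
        counts = confusion_counts(y_true.astype(str), y_pred.astype(str),
                                  classes[0])
        mcc = binary_metrics(counts)["MCC"]
    return EvaluationReport(accuracy=accuracy, recall=recall,
                            confusion=conf, mcc=mcc,
                            replication_index=replication_index)


def replicate_experiment(table: pd.DataFrame,
                         selector: Selector | None,
                         classifier_spec: ClassifierSpec,
                         split_spec: SplitSpec) -> ExperimentSummary:
    """The replicated protocol: split, select on train only, fit,
    score on the held-out test third.

    ``selector`` maps ``(train_table, seed) -> feature list`` (None
    keeps all features).  A replication whose selector returns nothing
    is flagged (report with NaN accuracy) and excluded from summaries.
    """
    reports: list[EvaluationReport] = []
    for rep in range(split_spec.n_replications):
        train, test = stratified_split(table, split_spec, rep)
        rep_seed = int(np.random.SeedSequence(
            (split_spec.seed, rep, 1)).generate_state(1)[0] % (2 ** 31))
        if selector is None:
            selected = tuple(c for c in table.columns if c != "label")
        else:
            selected = tuple(selector(train, rep_seed))
        if not selected:
            warnings.warn(f"replication {rep}: selector returned no "
                          "features; skipped")
            reports.append(EvaluationReport(
                accuracy=float("nan"), recall={}, confusion=pd.DataFrame(),
                replication_index=rep))
            continue
        clf = fit(train, selected, classifier_spec)
        y_pred = predict(clf, test)
        report = multiclass_report(test["label"].to_numpy(), y_pred,
                                   replication_index=rep)
        report.selected_features = selected
        reports.append(report)

    valid = [r for r in reports if not math.isnan(r.accuracy)]
    if not valid:
        raise ValueError("no replication produced a usable report")
    accs = np.array([r.accuracy for r in valid])
    classes = sorted({c for r in valid for c in r.recall})
    rec = {c: np.array([r.recall.get(c, 0.0) for r in valid])
           for c in classes}
    ddof = 1 if len(valid) > 1 else 0
    return ExperimentSummary(
        reports=reports,
        accuracy_mean=float(accs.mean()),
        accuracy_sd=float(accs.std(ddof=ddof)),
        recall_mean={c: float(v.mean()) for c, v in rec.items()},
        recall_sd={c: float(v.std(ddof=ddof)) for c, v in rec.items()},
    )
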