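"""One-vs-rest hierarchy over classes ordered by training-set size.

With c classes sorted by descending sample count, level i poses the
binary problem "i-th largest class (positive) vs all remaining smaller
classes (negative)"; the largest class is peeled off after its level, so
there are c - 1 levels and the last one opposes the two rarest classes.
Each level runs feature selection on its own training rows and reports
accuracy / MCC / recall plus the level's private feature subset per
replication.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from bmsf.classifiers import ClassifierSpec, fit, predict
from bmsf.evaluation import (
    Selector,
    SplitSpec,
    binary_metrics,
    confusion_counts,
    stratified_split,
)
from bmsf.selection import BMSFParams, bmsf_select

__all__ = ["HierarchyLevel", "build_hierarchy", "run_hierarchy"]

POSITIVE, NEGATIVE = "positive", "negative"


@dataclass
class HierarchyLevel:
    """One binary level of the cascade and its replicated results."""

    index: int                      # 1-based
    positive: str
    negatives: tuple[str, ...]
    accuracy: list[float] = field(default_factory=list)
    mcc: list[float] = field(default_factory=list)
    recall: list[float] = field(default_factory=list)
    private_subsets: list[tuple[str, ...]] = field(default_factory=list)
    flagged: list[int] = field(default_factory=list)  # skipped replications

    def summary(self) -> dict[str, float]:
        def ms(v: list[float]) -> tuple[float, float]:
            a = np.asarray(v, dtype=float)
            return (float(a.mean()), float(a.std(ddof=1 if len(a) > 1
                                                 else 0))) \
                if len(a) else (float("nan"), float("nan"))
        acc = ms(self.accuracy)
        mcc = ms(self.mcc)
        rec = ms(self.recall)
        return {"accuracy_mean": acc[0], "accuracy_sd": acc[1],
                "mcc_mean": mcc[0], "mcc_sd": mcc[1],
                "recall_mean": rec[0], "recall_sd": rec[1]}


def build_hierarchy(table: pd.DataFrame,
                    ) -> list[tuple[str, tuple[str, ...]]]:
    """Order classes by descending count (ties by name) and emit the
    c - 1 (positive, negatives) binary problems."""
    counts = table["label"].astype(str).value_counts()
    if len(counts) < 2:
        raise ValueError("need at least 2 classes")
    ordered = sorted(counts.index, key=lambda c: (-counts[c], c))
    return [(ordered[i], tuple(ordered[i + 1:]))
            for i in range(len(ordered) - 1)]


def _binarize(table: pd.DataFrame, positive: str) -> pd.DataFrame:
    out = table.copy()
    out["label"] = np.where(table["label"].astype(str) == positive,
                            POSITIVE, NEGATIVE)
    return out


def run_hierarchy(table: pd.DataFrame,
                  bmsf_params: BMSFParams,
                  classifier_spec: ClassifierSpec,
                  split_spec: SplitSpec,
                  selector: Selector | None = "bmsf",
                  ) -> list[HierarchyLevel]:
    """Run every level of the cascade with replicated 2:1 splits.

    Splits are stratified on the original class labels (so each neuron
    type keeps its own 2:1 ratio), then binarized.  ``selector`` is
    "bmsf" (default), None (keep all features), or any callable
    ``(train_table, seed) -> features``.  A replication whose test
    partition lacks one of the two binary classes is flagged and its
    metrics omitted.
    """
    levels = []
    for i, (positive, negatives) in enumerate(build_hierarchy(table),
                                              start=1):
        level = HierarchyLevel(index=i, positive=positive,
                               negatives=negatives)
        keep = table["label"].astype(str).isin({positive, *negatives})
        sub = table.loc[keep]
        for rep in range(split_spec.n_replications):
            train, test = stratified_split(sub, split_spec, rep)
            btrain, btest = _binarize(train, positive), _binarize(test,
                                                                  positive)
            if (len(set(btrain["label"])) < 2
                    or len(set(btest["label"])) < 2):
                level.flagged.append(rep)
                continue
            rep_seed = int(np.random.SeedSequence(
                (split_spec.seed, i, rep)).generate_state(1)[0] % (2 ** 31))
            if selector == "bmsf":
                result = bmsf_select(
                    btrain,
                    BMSFParams(k=bmsf_params.k,
                               cv_folds=bmsf_params.cv_folds,
                               classifier=bmsf_params.classifier,
                               max_rounds=bmsf_params.max_rounds,
                               min_features=bmsf_params.min_features,
                               seed=rep_seed))
                selected: Sequence[str] = result.selected
            elif selector is None:
                selected = tuple(c for c in sub.columns if c != "label")
            else:
                selected = tuple(selector(btrain, rep_seed))
            if not selected:
                level.flagged.append(rep)
                continue
            clf = fit(btrain, selected, classifier_spec)
            y_pred = predict(clf, btest)
            counts = confusion_counts(btest["label"].to_numpy(), y_pred,
                                      POSITIVE)
            metrics = binary_metrics(counts)
            level.accuracy.append(metrics["accuracy"])
            level.mcc.append(metrics["MCC"])
            level.recall.append(metrics["recall"])
            level.private_subsets.append(tuple(selected))
        levels.append(level)
    return levels
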