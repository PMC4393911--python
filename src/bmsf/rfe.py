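"""SVM-RFE: recursive feature elimination ranked by SVM weight magnitude.

Backward elimination in Guyon's original formulation: fit a linear-kernel
SVM on the surviving features, score each feature by the sum of its
squared weights across the one-vs-one machines, eliminate the single
worst feature, retrain, repeat.  Features are z-scored internally because
weight magnitudes are scale-sensitive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from bmsf.classifiers import split_xy

__all__ = ["RFERanking", "svm_rfe"]


@dataclass(frozen=True)
class RFERanking:
    """Full elimination order plus the requested top subset.

    ``elimination_order`` runs first-eliminated to last-eliminated;
    ``ranking`` is the reverse (best feature first).
    """

    elimination_order: tuple[str, ...]
    subset_size: int

    @property
    def ranking(self) -> tuple[str, ...]:
        return tuple(reversed(self.elimination_order))

    @property
    def subset(self) -> tuple[str, ...]:
        return self.ranking[: self.subset_size]


def _weight_criterion(X: np.ndarray, y: np.ndarray, seed: int) -> np.ndarray:
    """Per-feature sum of squared linear-SVM weights over all pairwise
    (one-vs-one) machines."""
    Xs = StandardScaler().fit_transform(X)
    clf = SVC(kernel="linear", C=1.0, decision_function_shape="ovo",
              random_state=seed)
    clf.fit(Xs, y)
    return np.sum(clf.coef_ ** 2, axis=0)


def svm_rfe(table: pd.DataFrame, subset_size: int, seed: int = 0,
            feature_subset: Sequence[str] | None = None) -> RFERanking:
    """Rank features by recursive elimination; return the top subset.

    One feature is eliminated per step (ties broken toward earlier
    column order); the SVM is retrained after every removal.
    """
    X, y, features = split_xy(table, feature_subset)
    if not np.issubdtype(X.dtype, np.number) or np.isnan(X).any():
        raise ValueError("features must be numeric and finite")
    if len(np.unique(y)) < 2:
        raise ValueError("need at least 2 classes")
    if not 1 <= subset_size <= len(features):
        raise ValueError(f"subset_size must be in [1, {len(features)}]")

    surviving = list(range(len(features)))
    eliminated: list[str] = []
    while len(surviving) > 1:
        crit = _weight_criterion(X[:, surviving], y, seed)
        worst = int(np.argmin(crit))  # argmin takes the first on ties
        eliminated.append(features[surviving[worst]])
        del surviving[worst]
    eliminated.append(features[surviving[0]])
    return RFERanking(elimination_order=tuple(eliminated),
                      subset_size=subset_size)
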