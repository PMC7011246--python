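"""Exhaustive-search feature-subset selection with a kernel SVM under LOO CV.

For subset sizes k = 1, 2, ... every size-k subset of the (reduced) feature
table is scored by leave-one-out accuracy of an RBF-kernel SVM; the search
stops when the best accuracy improves by no more than a threshold (default
1e-3) over the previous size, and the selected subset is the best one at the
last improving size.  Standardization happens strictly inside each training
fold (the held-out subject never touches the scaler), and every step is
deterministic: ties between subsets go to the lexicographically first subset
in canonical column order.

The RBF bandwidth follows gamma = 1 / (k * variance of the standardized
training matrix), i.e. sklearn's ``gamma='scale'`` applied after fold-wise
standardization; C defaults to 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .errors import ConfigurationError, DegenerateInputError


@dataclass
class SelectionConfig:
    kernel: str = "rbf"
    C: float = 1.0
    gamma: float | str = "scale"  # 'scale' = 1/(k * var of standardized training data)
    max_k: int = 5
    tol: float = 1e-3
    standardize: bool = True
    max_evaluations: int = 10_000_000
    force: bool = False

    def __post_init__(self) -> None:
        if self.tol <= 0:
            raise ConfigurationError(f"tol must be > 0, got {self.tol}")
        if self.C <= 0:
            raise ConfigurationError(f"C must be > 0, got {self.C}")
        if self.max_k < 1:
            raise ConfigurationError(f"max_k must be >= 1, got {self.max_k}")


@dataclass
class SelectionTrace:
    """Per-size best subsets/accuracies and the stopping decision."""

    levels: list[dict]  # {"k", "best_subset", "loo_accuracy", "n_subsets_evaluated"}
    stopped_at: int
    selected: list[str]
    selected_accuracy: float

    def to_dict(self) -> dict:
        return {
            "levels": self.levels,
            "stopped_at": self.stopped_at,
            "selected": self.selected,
            "selected_accuracy": self.selected_accuracy,
        }


def _encode_labels(labels) -> np.ndarray:
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size != 2:
        raise DegenerateInputError(f"need exactly 2 classes, got {classes.size}")
    return (y == classes[1]).astype(np.int64)


def loo_accuracy(X, labels, config: SelectionConfig | None = None) -> float:
    """Leave-one-out accuracy of the kernel SVM on one feature subset.

    ``X`` is an (n_subjects, n_features) array or DataFrame restricted to the
    subset under evaluation.
    """
    config = config or SelectionConfig()
    X = np.asarray(X, dtype=np.float64)
    if X.ndim == 1:
        X = X[:, None]
    y = _encode_labels(labels)
    n = X.shape[0]
    if min(int((y == 0).sum()), int((y == 1).sum())) < 2:
        raise DegenerateInputError("need >= 2 subjects per class for leave-one-out")
    correct = 0
    warned = False
    for i in range(n):
        tr = np.ones(n, dtype=bool)
        tr[i] = False
        Xtr, Xte = X[tr], X[i : i + 1]
        if np.unique(y[tr]).size < 2:
            raise DegenerateInputError("a training fold contains a single class")
        if config.standardize:
            mu = Xtr.mean(axis=0)
            sd = Xtr.std(axis=0)
            zero = sd == 0.0
            if zero.any() and not warned:
                warnings.warn("zero-variance column within a fold; standardized to 0")
                warned = True
            sd = np.where(zero, 1.0, sd)
            Xtr = (Xtr - mu) / sd
            Xte = (Xte - mu) / sd
            if zero.any():
                Xtr[:, zero] = 0.0
                Xte[:, zero] = 0.0
        clf = SVC(kernel=config.kernel, C=config.C, gamma=config.gamma)
        clf.fit(Xtr, y[tr])
        correct += int(clf.predict(Xte)[0] == y[i])
    return correct / n


def exhaustive_search(
    table: pd.DataFrame, labels, config: SelectionConfig | None = None
) -> SelectionTrace:
    """Grow subset size k, scoring every size-k subset, until the
    improvement-threshold stopping rule fires.

    best(0) := 0 so k = 1 is always evaluated.  When best(k) reaches 1.0 the
    next size cannot improve, so the rule fires without enumerating it.
    """
    config = config or SelectionConfig()
    cols = list(table.columns)
    p = len(cols)
    max_k = min(config.max_k, p)
    total = sum(comb(p, k) for k in range(1, max_k + 1))
    if total > config.max_evaluations and not config.force:
        raise ConfigurationError(
            f"{total} subset evaluations exceed the {config.max_evaluations} guard; "
            "reduce max_k/features or set force=True"
        )
    X = table.to_numpy(dtype=np.float64)
    y_raw = labels

    levels: list[dict] = []
    best_prev = 0.0
    selected: list[str] = []
    selected_acc = 0.0
    k = 0
    while k < max_k:
        k += 1
        if best_prev >= 1.0:  # no subset can improve on a perfect score
            levels.append(
                {"k": k, "best_subset": None, "loo_accuracy": None, "n_subsets_evaluated": 0}
            )
            break
        best_acc = -1.0
        best_subset: tuple[int, ...] | None = None
        n_eval = 0
        for subset in combinations(range(p), k):
            acc = loo_accuracy(X[:, subset], y_raw, config)
            n_eval += 1
            if acc > best_acc:  # strict '>' keeps the lexicographically first tie
                best_acc = acc
                best_subset = subset
        levels.append(
            {
                "k": k,
                "best_subset": [cols[i] for i in best_subset],
                "loo_accuracy": best_acc,
                "n_subsets_evaluated": n_eval,
            }
        )
        if best_acc - best_prev > config.tol:
            selected = [cols[i] for i in best_subset]
            selected_acc = best_acc
            best_prev = best_acc
        else:
            break
    return SelectionTrace(
        levels=levels, stopped_at=k, selected=selected, selected_accuracy=selected_acc
    )
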