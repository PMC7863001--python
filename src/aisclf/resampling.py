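"""Bootstrap class balancing and k-fold splitting.

Clinical recurrence cohorts are heavily imbalanced (here 38 recurrent vs
561 non-recurrent); classifiers trained on the raw data overfit the large
class and the small class goes unrecognized.  ``bootstrap_balance``
resamples the minority class with replacement until the two classes are
equal in size — plain resampling, not synthetic interpolation.

By default balancing is applied per training fold only (``balance_scope:
fold``), so duplicated minority rows never straddle a train/test boundary.
Balancing the whole dataset before splitting (``balance_scope: global``)
is also available: it reproduces the historical protocol of balancing
first and evaluating afterwards, at the cost of duplicate leakage across
folds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import KFold, StratifiedKFold

from .data_model import FeatureTable


@dataclass
class FoldPlan:
    """A k-fold partition of row indices."""

    k: int
    folds: list[np.ndarray]
    stratified: bool

    def validate(self, n: int) -> None:
        """Assert the partition invariants: folds are disjoint, cover all
        rows, and differ in size by at most one."""
        all_idx = np.concatenate(self.folds)
        if len(all_idx) != n or len(np.unique(all_idx)) != n:
            raise AssertionError("folds do not partition the index set")
        sizes = [len(f) for f in self.folds]
        if max(sizes) - min(sizes) > 1:
            raise AssertionError("fold sizes differ by more than 1")

    def train_test(self, fold: int, n: int) -> tuple[np.ndarray, np.ndarray]:
        test = self.folds[fold]
        mask = np.ones(n, dtype=bool)
        mask[test] = False
        return np.flatnonzero(mask), test


def bootstrap_balance(table: FeatureTable, seed: int = 0) -> FeatureTable:
    """Resample the minority class with replacement up to the majority count.

    All original rows pass through unchanged and in order; the resampled
    minority copies are appended at the end.  Every appended row is an
    exact copy of some original minority row.  Deterministic given seed.
    """
    if table.labels is None:
        raise ValueError("bootstrap_balance requires a labeled table")
    classes, counts = np.unique(table.labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("bootstrap_balance requires at least two classes")
    if len(classes) != 2:
        raise ValueError("bootstrap_balance supports binary labels only")
    if counts[0] == counts[1]:
        return table.copy()
    minority = classes[np.argmin(counts)]
    deficit = int(abs(counts[0] - counts[1]))
    minority_rows = np.flatnonzero(table.labels == minority)
    rng = np.random.default_rng(seed)
    extra = rng.choice(minority_rows, size=deficit, replace=True)
    idx = np.concatenate([np.arange(table.n_samples), extra])
    return table.select_rows(idx)


def kfold_indices(
    n: int,
    k: int,
    labels: np.ndarray | None = None,
    seed: int = 0,
) -> FoldPlan:
    """Shuffled k-fold plan over ``n`` rows, stratified when labels given."""
    if k < 2:
        raise ValueError("k must be at least 2")
    if k > n:
        raise ValueError("k must not exceed the number of rows")
    if labels is not None:
        labels = np.asarray(labels)
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        split = splitter.split(np.zeros(n), labels)
    else:
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
        split = splitter.split(np.zeros(n))
    folds = [np.sort(test) for _, test in split]
    plan = FoldPlan(k=k, folds=folds, stratified=labels is not None)
    plan.validate(n)
    return plan
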