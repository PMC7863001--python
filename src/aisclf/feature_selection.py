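"""Feature selection: the SFS-AIS wrapper and two filter baselines.

SFS-AIS wraps the immune classifier in a sequential elimination loop:
starting from the full feature set, each round refits and cross-validates
the classifier with every single remaining feature left out, removes the
feature whose exclusion yields the highest recognition rate (accuracy),
and repeats until the target subset size (default 11 of 20) remains.  A
forward-growing variant is available for comparison.

The filter baselines are classic Relief (nearest hit/miss differences on
the normalized scale) and information gain (entropy reduction of the
class label, continuous features discretized into equal-frequency bins).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .ais_core import AISConfig, fit_ais, predict_ais
from .data_model import FeatureTable, normalize_minmax
from .resampling import bootstrap_balance, kfold_indices


@dataclass
class FeatureSubset:
    """An ordered set of selected features (1-based indices, matching the
    registry's variable numbering) plus the per-round selection trace."""

    selected: list[int]
    trace: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(set(self.selected)) != len(self.selected):
            raise ValueError("selected indices must be unique")


# --------------------------------------------------------------------------
# SFS-AIS wrapper
# --------------------------------------------------------------------------

# Wrapper-internal AIS settings: fewer refinement rounds than the default
# classifier because the wrapper fits the model hundreds of times and the
# ranking of candidate subsets stabilizes long before full convergence.
_WRAPPER_AIS = AISConfig(max_iterations=15)


def recognition_rate(
    table: FeatureTable,
    feature_idx: list[int],
    ais_config: AISConfig,
    cv_folds: int = 3,
    seed: int = 0,
    balance: bool = True,
) -> float:
    """Cross-validated accuracy of the immune classifier on a column
    subset (0-based); the training portion of each fold is bootstrap
    balanced so the minority class is not ignored."""
    sub = table.select_features(feature_idx)
    plan = kfold_indices(sub.n_samples, cv_folds, sub.labels, seed=seed)
    correct = 0
    for f in range(plan.k):
        tr_idx, te_idx = plan.train_test(f, sub.n_samples)
        train = sub.select_rows(tr_idx)
        if balance:
            train = bootstrap_balance(train, seed=seed + f)
        train_n, params = normalize_minmax(train)
        model = fit_ais(train_n, replace(ais_config, seed=seed))
        X_test = params.apply(sub.values[te_idx])
        pred, _ = predict_ais(model, X_test)
        correct += int(np.sum(pred == sub.labels[te_idx]))
    return correct / sub.n_samples


def sfs_ais_select(
    table: FeatureTable,
    target_k: int = 11,
    ais_config: AISConfig | None = None,
    seed: int = 0,
    cv_folds: int = 3,
    direction: str = "backward",
) -> FeatureSubset:
    """Wrapper feature selection around the immune classifier.

    ``backward`` (default) eliminates one feature per round — the one
    whose removal gives the highest cross-validated recognition rate,
    ties broken toward removing the larger index — until ``target_k``
    features remain.  ``forward`` grows the subset greedily instead.
    """
    if table.labels is None:
        raise ValueError("sfs_ais_select requires labels")
    if target_k >= table.n_features:
        raise ValueError("target_k must be smaller than the feature count")
    config = ais_config or _WRAPPER_AIS
    trace: list[dict] = []

    if direction == "backward":
        remaining = list(range(table.n_features))  # 0-based
        while len(remaining) > target_k:
            rates = []
            for f in remaining:
                candidate = [g for g in remaining if g != f]
                rates.append(recognition_rate(table, candidate, config, cv_folds, seed))
            rates = np.array(rates)
            # highest rate wins; ties -> remove the larger feature index
            best_rate = rates.max()
            tied = [remaining[i] for i in np.flatnonzero(rates >= best_rate - 1e-12)]
            removed = max(tied)
            trace.append(
                {
                    "removed": removed + 1,
                    "rate": float(best_rate),
                    "candidates": {remaining[i] + 1: float(r) for i, r in enumerate(rates)},
                }
            )
            remaining.remove(removed)
        selected = sorted(i + 1 for i in remaining)
    elif direction == "forward":
        chosen: list[int] = []
        pool = list(range(table.n_features))
        while len(chosen) < target_k:
            rates = []
            for f in pool:
                rates.append(recognition_rate(table, chosen + [f], config, cv_folds, seed))
            rates = np.array(rates)
            best_rate = rates.max()
            tied = [pool[i] for i in np.flatnonzero(rates >= best_rate - 1e-12)]
            added = min(tied)
            trace.append({"added": added + 1, "rate": float(best_rate)})
            chosen.append(added)
            pool.remove(added)
        selected = sorted(i + 1 for i in chosen)
    else:
        raise ValueError("direction must be 'backward' or 'forward'")
    return FeatureSubset(selected=selected, trace=trace)


# --------------------------------------------------------------------------
# Relief
# --------------------------------------------------------------------------


def relief_scores(
    table: FeatureTable,
    n_neighbors: int = 1,
    n_iterations: int | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Classic Relief feature weights for a binary-labeled table.

    Per sampled instance the score of feature f gains diff(f, x, nearest
    miss) and loses diff(f, x, nearest hit).  As in classic Relief, diff is
    the absolute difference on the min-max normalized scale for continuous
    and ordinal features and a 0/1 mismatch indicator for nominal and
    binary codes; neighbor search uses the summed per-feature diffs.  By
    default every sample is visited once (deterministic); ``n_iterations``
    subsamples instead.
    """
    if table.labels is None:
        raise ValueError("relief_scores requires labels")
    if n_neighbors != 1:
        raise ValueError("only the single-neighbor classic Relief is implemented")
    norm, _ = normalize_minmax(table)
    X, y = norm.values, table.labels
    n = X.shape[0]
    categorical = np.array([k in ("nominal", "binary") for k in table.feature_kinds])
    D = np.zeros((n, n))
    for j in range(X.shape[1]):
        dj = np.abs(X[:, j][:, None] - X[:, j][None, :])
        if categorical[j]:
            dj = (dj > 1e-12).astype(float)
        D += dj
    np.fill_diagonal(D, np.inf)

    rng = np.random.default_rng(seed)
    if n_iterations is None or n_iterations >= n:
        visits = np.arange(n)
    else:
        visits = rng.choice(n, size=n_iterations, replace=False)

    scores = np.zeros(X.shape[1])
    used = 0
    for i in visits:
        same = (y == y[i]).copy()
        same[i] = False
        if not same.any():
            warnings.warn(f"class {y[i]} has a single sample; skipped", stacklevel=2)
            continue
        hit = np.flatnonzero(same)[np.argmin(D[i, same])]
        miss_mask = y != y[i]
        miss = np.flatnonzero(miss_mask)[np.argmin(D[i, miss_mask])]
        diff_miss = np.abs(X[i] - X[miss])
        diff_hit = np.abs(X[i] - X[hit])
        diff_miss[categorical] = (diff_miss[categorical] > 1e-12).astype(float)
        diff_hit[categorical] = (diff_hit[categorical] > 1e-12).astype(float)
        scores += diff_miss - diff_hit
        used += 1
    return scores / max(used, 1)


# --------------------------------------------------------------------------
# Information gain
# --------------------------------------------------------------------------


def _entropy(counts: np.ndarray) -> float:
    p = counts / counts.sum()
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def info_gain_scores(table: FeatureTable, n_bins: int = 10) -> np.ndarray:
    """Information gain of each feature about the class label, in bits.

    Continuous features are discretized into ``n_bins`` equal-frequency
    bins; coded features use their integer codes directly.
    """
    if table.labels is None:
        raise ValueError("info_gain_scores requires labels")
    y = table.labels
    h_y = _entropy(np.bincount(y))
    scores = np.zeros(table.n_features)
    for j, kind in enumerate(table.feature_kinds):
        col = table.values[:, j]
        if kind == "continuous":
            binned = pd.qcut(col, q=n_bins, labels=False, duplicates="drop")
            binned = np.nan_to_num(np.asarray(binned, dtype=float), nan=0).astype(int)
        else:
            binned = col.astype(int)
        h_cond = 0.0
        for v in np.unique(binned):
            mask = binned == v
            h_cond += mask.mean() * _entropy(np.bincount(y[mask]))
        scores[j] = max(0.0, h_y - h_cond)
    return scores


def select_top_k(scores: np.ndarray, k: int) -> FeatureSubset:
    """Indices (1-based) of the k largest scores; ties keep the smaller
    index first."""
    scores = np.asarray(scores, dtype=float)
    if k > len(scores):
        raise ValueError("k exceeds the number of features")
    order = np.argsort(-scores, kind="stable")
    return FeatureSubset(selected=[int(i) + 1 for i in order[:k]])
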