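"""Confusion-matrix metrics, ROC curves, and the benchmark runner.

Metric conventions follow clinical reporting: accuracy, sensitivity,
specificity, PPV and NPV as percentages, with explicit *undefined*
semantics when a denominator is zero — e.g. a classifier that never
predicts recurrence on a cohort with no detected recurrent cases has
sensitivity undefined (rendered ``NaN`` in text reports), PPV 0 and
NPV 100, while accuracy equals specificity.  Ratios are never silently
coerced to 0 or 100.

``run_benchmark`` evaluates the five classifiers (BPNN, SVM, FCM, AK,
AIS) under cross-validation, with and without bootstrap balancing of the
training folds, on the full feature set and an optional selected subset,
pooling held-out confusion counts across folds (micro-averaging) and
collecting per-fold metrics and ROC scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve as _sk_roc_curve

from . import baselines
from .ais_core import AISConfig, fit_ais, predict_ais
from .data_model import FeatureTable, normalize_minmax
from .feature_selection import info_gain_scores, select_top_k
from .resampling import bootstrap_balance, kfold_indices

CLASSIFIERS = ("bpnn", "svm", "fcm", "ak", "ais")


@dataclass
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.TP + other.TP, self.FP + other.FP, self.TN + other.TN, self.FN + other.FN
        )


@dataclass
class MetricSet:
    """The five clinical rates as percentages; ``None`` marks an undefined
    ratio (zero denominator)."""

    accuracy: float | None
    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None

    def render(self, name: str) -> str:
        def fmt(v: float | None) -> str:
            return "NaN" if v is None else f"{v:.2f}"

        return (
            f"{name}: accuracy {fmt(self.accuracy)} | sensitivity {fmt(self.sensitivity)} | "
            f"specificity {fmt(self.specificity)} | PPV {fmt(self.ppv)} | NPV {fmt(self.npv)}"
        )


@dataclass
class ROCResult:
    points: np.ndarray  # (m, 2) columns FPR, TPR; starts (0,0) ends (1,1)
    auc: float


def confusion_counts(truth: np.ndarray, predicted: np.ndarray) -> ConfusionCounts:
    """Tally a binary confusion matrix; the positive class is recurrence
    (label 1)."""
    truth = np.asarray(truth)
    predicted = np.asarray(predicted)
    if truth.shape != predicted.shape:
        raise ValueError("truth and predicted must have equal length")
    return ConfusionCounts(
        TP=int(np.sum((truth == 1) & (predicted == 1))),
        FP=int(np.sum((truth == 0) & (predicted == 1))),
        TN=int(np.sum((truth == 0) & (predicted == 0))),
        FN=int(np.sum((truth == 1) & (predicted == 0))),
    )


def _ratio(num: int, den: int) -> float | None:
    return None if den == 0 else 100.0 * num / den


def metrics_from_counts(c: ConfusionCounts) -> MetricSet:
    if c.total == 0:
        raise ValueError("cannot compute metrics on zero samples")
    return MetricSet(
        accuracy=_ratio(c.TP + c.TN, c.total),
        sensitivity=_ratio(c.TP, c.TP + c.FN),
        specificity=_ratio(c.TN, c.TN + c.FP),
        ppv=_ratio(c.TP, c.TP + c.FP),
        npv=_ratio(c.TN, c.TN + c.FN),
    )


def roc_curve(scores: np.ndarray, truth: np.ndarray) -> ROCResult:
    """Threshold-sweep ROC with trapezoidal AUC; tied scores are grouped
    at a single threshold."""
    truth = np.asarray(truth)
    scores = np.asarray(scores, dtype=float)
    if truth.shape != scores.shape:
        raise ValueError("scores and truth must have equal length")
    if len(np.unique(truth)) < 2:
        raise ValueError("ROC needs at least one positive and one negative")
    fpr, tpr, _ = _sk_roc_curve(truth, scores, drop_intermediate=False)
    pts = np.column_stack([fpr, tpr])
    auc = float(np.trapezoid(tpr, fpr))
    return ROCResult(points=pts, auc=auc)


def average_metrics(per_fold: list[MetricSet]) -> tuple[MetricSet, dict[str, int]]:
    """Macro-average fold metrics, skipping undefined values; the second
    return reports how many folds were skipped per metric."""
    fields = ("accuracy", "sensitivity", "specificity", "ppv", "npv")
    means: dict[str, float | None] = {}
    skipped: dict[str, int] = {}
    for f in fields:
        vals = [getattr(ms, f) for ms in per_fold if getattr(ms, f) is not None]
        skipped[f] = len(per_fold) - len(vals)
        means[f] = float(np.mean(vals)) if vals else None
    return MetricSet(**means), skipped


# --------------------------------------------------------------------------
# Benchmark runner
# --------------------------------------------------------------------------


@dataclass
class BenchmarkConfig:
    """Protocol knobs for the Table-style benchmark.

    ``arms`` selects training-fold treatment: ``none`` (raw imbalanced
    training data) and/or ``bootstrap`` (fold-scoped bootstrap balancing;
    ``balance_scope='global'`` instead balances the whole dataset before
    splitting).  ``feature_sets`` maps a name to 1-based feature indices,
    or ``None`` for all features; the special name ``"selected"`` with
    value ``None`` triggers an information-gain top-``selected_k`` pick
    on the full data.
    """

    k_folds: int = 10
    seed: int = 0
    classifiers: tuple[str, ...] = CLASSIFIERS
    arms: tuple[str, ...] = ("none", "bootstrap")
    balance_scope: str = "fold"  # "fold" | "global"
    feature_sets: dict = field(default_factory=lambda: {"all": None})
    selected_k: int = 11
    ais: AISConfig = field(default_factory=AISConfig)
    bpnn_epochs: int = 1000
    bpnn_lr: float = 0.1
    svm_C: float = 1.0
    svm_gamma: float | None = None
    fcm_m: float = 2.0
    ak_rho: float = 0.1


@dataclass
class BenchmarkReport:
    rows: pd.DataFrame  # one row per classifier x arm x feature set
    rocs: dict[tuple[str, str, str], ROCResult]
    per_fold: dict[tuple[str, str, str], list[MetricSet]]

    def render(self) -> str:
        """Text table in the conventional column order (Accuracy,
        Sensitivity, Specificity, PPV, NPV), undefined rendered as NaN."""
        lines = []
        df = self.rows
        for _, r in df.iterrows():
            ms = MetricSet(r["accuracy"], r["sensitivity"], r["specificity"], r["ppv"], r["npv"])
            ms = MetricSet(*[None if pd.isna(v) else v for v in
                             (ms.accuracy, ms.sensitivity, ms.specificity, ms.ppv, ms.npv)])
            lines.append(ms.render(f"{r['classifier']:>4s} [{r['arm']:>9s}] ({r['features']})"))
        return "\n".join(lines)


def _fit_predict(
    name: str,
    train: FeatureTable,
    X_test: np.ndarray,
    config: BenchmarkConfig,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Fit one classifier on a normalized training table and score the
    normalized test matrix.  Returns (predicted class, positive-class
    score) — for the clusterers, clusters are mapped to classes by
    majority vote on the training assignments."""
    y = train.labels
    if name == "bpnn":
        model = baselines.fit_bpnn(train, config.bpnn_epochs, config.bpnn_lr, seed)
        return baselines.predict_bpnn(model, X_test)
    if name == "svm":
        model = baselines.fit_svm(train, config.svm_C, config.svm_gamma)
        return baselines.predict_svm(model, X_test)
    if name == "ais":
        model = fit_ais(train, replace(config.ais, seed=seed))
        pred, _ = predict_ais(model, X_test)
        probs = model.hormone.probabilities_batch(X_test)
        pos = int(np.flatnonzero(model.hormone.classes == 1)[0])
        return pred, probs[:, pos]
    if name == "fcm":
        model = baselines.fit_fcm(train, c=2, m=config.fcm_m, seed=seed)
        train_assign = np.argmax(model.membership, axis=1)
        mapping = baselines.map_clusters_to_classes(train_assign, y)
        clusters, U = baselines.predict_fcm(model, X_test)
        pos_clusters = [cl for cl, c in mapping.items() if c == 1]
        score = U[:, pos_clusters].sum(axis=1) if pos_clusters else np.zeros(len(U))
        pred = np.array([mapping[int(cl)] for cl in clusters])
        return pred, score
    if name == "ak":
        model = baselines.fit_ak(train, k=2, rho=config.ak_rho, seed=seed)
        train_assign = np.argmax(model.assign_probs, axis=1)
        mapping = baselines.map_clusters_to_classes(train_assign, y)
        clusters, probs = baselines.predict_ak(model, X_test)
        pos_clusters = [cl for cl, c in mapping.items() if c == 1]
        score = probs[:, pos_clusters].sum(axis=1) if pos_clusters else np.zeros(len(probs))
        pred = np.array([mapping[int(cl)] for cl in clusters])
        return pred, score
    raise ValueError(f"unknown classifier {name!r}")


def run_benchmark(cohort: FeatureTable, config: BenchmarkConfig | None = None) -> BenchmarkReport:
    """Cross-validated comparison of all classifiers and arms.

    Confusion counts are pooled over held-out folds and converted to
    metrics once (micro-averaging); per-fold macro metrics and pooled ROC
    scores are kept alongside.
    """
    config = config or BenchmarkConfig()
    if cohort.labels is None:
        raise ValueError("benchmark requires a labeled cohort")

    feature_sets: dict[str, list[int] | None] = {}
    for fname, idx in config.feature_sets.items():
        if idx is None and fname == "selected":
            scores = info_gain_scores(cohort)
            idx = select_top_k(scores, config.selected_k).selected
        feature_sets[fname] = idx

    records = []
    rocs: dict[tuple[str, str, str], ROCResult] = {}
    per_fold_all: dict[tuple[str, str, str], list[MetricSet]] = {}

    for fname, idx in feature_sets.items():
        data = cohort if idx is None else cohort.select_features([i - 1 for i in idx])
        for arm in config.arms:
            working = data
            if arm == "bootstrap" and config.balance_scope == "global":
                working = bootstrap_balance(data, seed=config.seed)
            plan = kfold_indices(working.n_samples, config.k_folds, working.labels, config.seed)
            fold_data = []
            for f in range(plan.k):
                tr_idx, te_idx = plan.train_test(f, working.n_samples)
                train = working.select_rows(tr_idx)
                if arm == "bootstrap" and config.balance_scope == "fold":
                    train = bootstrap_balance(train, seed=config.seed + f)
                train_n, params = normalize_minmax(train)
                X_test = params.apply(working.values[te_idx])
                fold_data.append((train_n, X_test, working.labels[te_idx]))
            for name in config.classifiers:
                pooled = ConfusionCounts(0, 0, 0, 0)
                fold_metrics = []
                all_scores, all_truth = [], []
                for f, (train_n, X_test, y_test) in enumerate(fold_data):
                    pred, score = _fit_predict(name, train_n, X_test, config, config.seed + f)
                    counts = confusion_counts(y_test, pred)
                    pooled = pooled + counts
                    fold_metrics.append(metrics_from_counts(counts))
                    all_scores.append(score)
                    all_truth.append(y_test)
                ms = metrics_from_counts(pooled)
                key = (name, arm, fname)
                per_fold_all[key] = fold_metrics
                scores_cat = np.concatenate(all_scores)
                truth_cat = np.concatenate(all_truth)
                if len(np.unique(truth_cat)) == 2:
                    rocs[key] = roc_curve(scores_cat, truth_cat)
                records.append(
                    {
                        "classifier": name,
                        "arm": arm,
                        "features": fname,
                        "n_features": data.n_features,
                        "TP": pooled.TP,
                        "FP": pooled.FP,
                        "TN": pooled.TN,
                        "FN": pooled.FN,
                        "accuracy": np.nan if ms.accuracy is None else ms.accuracy,
                        "sensitivity": np.nan if ms.sensitivity is None else ms.sensitivity,
                        "specificity": np.nan if ms.specificity is None else ms.specificity,
                        "ppv": np.nan if ms.ppv is None else ms.ppv,
                        "npv": np.nan if ms.npv is None else ms.npv,
                        "auc": rocs[key].auc if key in rocs else np.nan,
                        "seed": config.seed,
                    }
                )
    return BenchmarkReport(rows=pd.DataFrame.from_records(records), rocs=rocs, per_fold=per_fold_all)
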