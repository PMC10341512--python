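"""Predictive metabolite panels by greedy forward selection inside
repeated stratified nested cross-validation with a linear soft-margin SVM.

Outer folds estimate generalization; inner folds (within each outer
training partition) drive the forward selection, so no held-out sample
ever influences standardization or which features are chosen — the
leakage-avoidance property the nested layout exists for. Selection walks
forward from the empty set, at each step adding the feature that maximizes
mean inner-CV accuracy, capped at a fraction of all features (default
50%); the panel actually used on the outer test fold is the earliest
prefix of the path attaining the maximal inner accuracy. Fold-level panels
are merged into one reported panel by selection frequency.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

__all__ = ["PanelReport", "train_linear_margin_classifier",
           "greedy_forward_select", "nested_cv_evaluate", "aggregate_panel"]


def train_linear_margin_classifier(X, y, cost: float = 1.0):
    """Fit a linear soft-margin SVM; returns (weights, bias).

    Minimizes hinge loss plus an L2 margin penalty with box constraint
    ``cost``; prediction is sign(w·x + b). Deterministic for fixed input.
    ``y`` must hold exactly two classes coded ±1.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(np.unique(y)) != 2:
        raise ValueError("need exactly two classes")
    if cost <= 0:
        raise ValueError("cost must be positive")
    clf = SVC(kernel="linear", C=cost)
    clf.fit(X, y)
    return clf.coef_.ravel(), float(clf.intercept_[0])


def _fold_standardize(X_tr: np.ndarray, X_te: np.ndarray):
    """z-score both partitions with training-fold parameters only."""
    mu = X_tr.mean(axis=0)
    sd = X_tr.std(axis=0, ddof=1)
    sd = np.where(sd < 1e-12, 1.0, sd)
    return (X_tr - mu) / sd, (X_te - mu) / sd


def _inner_accuracy(folds, cols, cost) -> float:
    """Mean held-out accuracy over pre-standardized inner folds for a
    feature subset given as column indices."""
    correct = total = 0
    for Xtr, ytr, Xte, yte in folds:
        clf = SVC(kernel="linear", C=cost)
        clf.fit(Xtr[:, cols], ytr)
        correct += int((clf.predict(Xte[:, cols]) == yte).sum())
        total += len(yte)
    return correct / total


def greedy_forward_select(X_train, y_train, *, inner_folds: int = 3,
                          cost: float = 1.0, max_fraction: float = 0.5,
                          seed: int = 0):
    """Greedy wrapper selection maximizing inner-CV accuracy.

    Returns (path, accuracy_path, best_prefix_length): ``path`` is the
    ordered list of chosen column indices, capped at
    floor(max_fraction × n_features); ``best_prefix_length`` marks the
    earliest prefix attaining the maximal inner accuracy. Accuracy ties
    between candidate features break toward the lower column index.
    """
    X = np.asarray(X_train, dtype=float)
    y = np.asarray(y_train)
    n, d = X.shape
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("need exactly two classes")
    if counts.min() < inner_folds:
        raise ValueError(f"smallest class ({counts.min()}) below "
                         f"inner fold count {inner_folds}")
    cv = StratifiedKFold(n_splits=inner_folds, shuffle=True, random_state=seed)
    folds = []
    for tr, te in cv.split(X, y):
        Xtr, Xte = _fold_standardize(X[tr], X[te])
        folds.append((Xtr, y[tr], Xte, y[te]))

    cap = max(1, int(np.floor(max_fraction * d)))
    path: list[int] = []
    acc_path: list[float] = []
    remaining = list(range(d))
    while len(path) < cap:
        best_feat, best_acc = None, -1.0
        for f in remaining:
            acc = _inner_accuracy(folds, path + [f], cost)
            if acc > best_acc:
                best_feat, best_acc = f, acc
        path.append(best_feat)
        acc_path.append(best_acc)
        remaining.remove(best_feat)
    best_len = int(np.argmax(acc_path)) + 1   # earliest maximal prefix
    return path, acc_path, best_len


@dataclass
class PanelReport:
    """Nested-CV performance plus the aggregated predictive panel."""

    accuracy: float                 # percentages over pooled outer-test predictions
    sensitivity: float
    specificity: float
    balanced_accuracy: float
    panel: pd.DataFrame             # aggregated panel with selection frequencies
    fold_records: list = field(default_factory=list)
    config: dict = field(default_factory=dict)

    def metrics(self) -> dict[str, float]:
        return {"accuracy": self.accuracy, "sensitivity": self.sensitivity,
                "specificity": self.specificity,
                "balanced_accuracy": self.balanced_accuracy}


def nested_cv_evaluate(X, y, positive_label, *, repeats: int = 10,
                       outer_folds: int = 3, inner_folds: int = 3,
                       cost: float = 1.0, max_fraction: float = 0.5,
                       seed: int = 0,
                       feature_names=None,
                       univariate_p: pd.Series | None = None) -> PanelReport:
    """Repeated stratified nested CV with forward selection per outer fold.

    Sensitivity is the true-positive rate of ``positive_label`` (by
    convention the first-named, treatment/condition group of a comparison).
    Metrics are percentages computed over outer-test predictions pooled
    across all repeats and folds. Identical seeds reproduce the report
    exactly.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n, d = X.shape
    if feature_names is None:
        feature_names = [f"feature_{j}" for j in range(d)]
    feature_names = list(feature_names)
    classes, counts = np.unique(y, return_counts=True)
    if positive_label not in classes:
        raise ValueError(f"positive label {positive_label!r} not in labels")
    if counts.min() < outer_folds:
        raise ValueError(
            f"smallest class has {counts.min()} samples, fewer than "
            f"outer_folds={outer_folds}; reduce the fold count or simulate "
            "larger groups")

    tp = tn = fp = fn = 0
    fold_records = []
    for rep in range(repeats):
        rep_seed = (seed + 7919 * rep) % (2**31 - 1)
        outer = StratifiedKFold(n_splits=outer_folds, shuffle=True,
                                random_state=rep_seed)
        for k, (tr, te) in enumerate(outer.split(X, y)):
            path, acc_path, best_len = greedy_forward_select(
                X[tr], y[tr], inner_folds=inner_folds, cost=cost,
                max_fraction=max_fraction, seed=rep_seed + k)
            panel_idx = path[:best_len]
            Xtr, Xte = _fold_standardize(X[tr][:, panel_idx],
                                         X[te][:, panel_idx])
            clf = SVC(kernel="linear", C=cost)
            clf.fit(Xtr, y[tr])
            pred = clf.predict(Xte)
            pos = y[te] == positive_label
            hit = pred == y[te]
            tp += int((pos & hit).sum()); fn += int((pos & ~hit).sum())
            tn += int((~pos & hit).sum()); fp += int((~pos & ~hit).sum())
            fold_records.append({
                "repeat": rep, "fold": k,
                "path": [feature_names[j] for j in path],
                "inner_accuracy_path": list(acc_path),
                "panel": [feature_names[j] for j in panel_idx]})

    sens = 100.0 * tp / (tp + fn) if tp + fn else 0.0
    spec = 100.0 * tn / (tn + fp) if tn + fp else 0.0
    acc = 100.0 * (tp + tn) / (tp + tn + fp + fn)
    panel = aggregate_panel(fold_records, univariate_p=univariate_p)
    return PanelReport(
        accuracy=acc, sensitivity=sens, specificity=spec,
        balanced_accuracy=(sens + spec) / 2.0,
        panel=panel, fold_records=fold_records,
        config={"repeats": repeats, "outer_folds": outer_folds,
                "inner_folds": inner_folds, "cost": cost,
                "max_fraction": max_fraction, "seed": seed,
                "positive_label": positive_label})


def aggregate_panel(fold_records: list[dict],
                    univariate_p: pd.Series | None = None) -> pd.DataFrame:
    """Merge fold-level panels into one reported panel.

    Features are ranked by selection frequency across all outer folds and
    repeats, ties broken by mean inner accuracy at first inclusion, then by
    univariate p (when given), then by name. The reported panel size is the
    modal size of the fold-level best prefixes (ties toward the smaller
    size). Returns every selected feature with its frequency and an
    ``in_panel`` flag for the top ``panel size`` rows.
    """
    if not fold_records:
        raise ValueError("no fold panels to aggregate")
    n_folds = len(fold_records)
    freq: dict[str, int] = {}
    acc_at_inclusion: dict[str, list[float]] = {}
    sizes = []
    for rec in fold_records:
        sizes.append(len(rec["panel"]))
        for pos, feat in enumerate(rec["panel"]):
            freq[feat] = freq.get(feat, 0) + 1
            acc_at_inclusion.setdefault(feat, []).append(
                rec["inner_accuracy_path"][pos])
    size_counts = pd.Series(sizes).value_counts()
    modal_size = int(size_counts[size_counts == size_counts.max()].index.min())

    rows = []
    for feat, count in freq.items():
        p = float(univariate_p.get(feat, np.nan)) if univariate_p is not None \
            else np.nan
        rows.append({"metabolite": feat,
                     "selection_frequency": count / n_folds,
                     "mean_inner_accuracy": float(np.mean(acc_at_inclusion[feat])),
                     "p_raw": p})
    out = pd.DataFrame(rows)
    out["_p"] = out["p_raw"].fillna(np.inf)
    out = out.sort_values(
        by=["selection_frequency", "mean_inner_accuracy", "_p", "metabolite"],
        ascending=[False, False, True, True]).drop(columns="_p")
    out = out.reset_index(drop=True)
    out["in_panel"] = out.index < modal_size
    return out.set_index("metabolite")
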