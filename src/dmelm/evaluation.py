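"""Confusion-matrix metrics, stratified cross-validation, activation sweep
and validation curves.

Multi-class sensitivity, specificity and F-score are macro-averaged
one-vs-rest quantities (the unweighted mean of the per-class rates); any
0/0 ratio is defined as 0 so degenerate classifiers still produce bounded
reports.  Cross-validated results are reported as mean ± std over the
fold-level metric values, with the population (divisor-k) std.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.model_selection import StratifiedKFold

from .elm import ACTIVATION_KINDS, ELM, ELMConfig
from .io_eeg import LABEL_COLUMN

__all__ = [
    "ConfusionMatrix",
    "MetricSet",
    "MetricReport",
    "confusion",
    "metrics",
    "stratified_folds",
    "cross_validate",
    "elm_classifier_factory",
    "activation_sweep",
    "validation_curve",
]


@dataclass
class ConfusionMatrix:
    """C x C counts; rows are true classes, columns predicted classes."""

    counts: np.ndarray
    class_names: tuple

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        C = len(self.class_names)
        if self.counts.shape != (C, C):
            raise ValueError("counts must be square and match class_names")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class MetricSet:
    accuracy: float
    sensitivity: float
    specificity: float
    f_score: float

    def as_array(self) -> np.ndarray:
        return np.array([self.accuracy, self.sensitivity, self.specificity, self.f_score])


def confusion(true_labels, predicted_labels, class_names: Sequence) -> ConfusionMatrix:
    """Tally a confusion matrix over a fixed class order."""
    true_labels = list(true_labels)
    predicted_labels = list(predicted_labels)
    if len(true_labels) != len(predicted_labels):
        raise ValueError("label sequences have different lengths")
    known = set(class_names)
    for lab in (*true_labels, *predicted_labels):
        if lab not in known:
            raise ValueError(f"label {lab!r} not in class_names {tuple(class_names)}")
    counts = _sk_confusion(true_labels, predicted_labels, labels=list(class_names))
    return ConfusionMatrix(counts=counts, class_names=tuple(class_names))


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else 0.0


def metrics(cm: ConfusionMatrix) -> MetricSet:
    """Accuracy plus macro one-vs-rest sensitivity, specificity and F-score."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    counts = cm.counts.astype(float)
    total = counts.sum()
    accuracy = np.trace(counts) / total
    sens, spec, fscores = [], [], []
    for i in range(len(cm.class_names)):
        tp = counts[i, i]
        fn = counts[i, :].sum() - tp
        fp = counts[:, i].sum() - tp
        tn = total - tp - fn - fp
        recall = _safe_div(tp, tp + fn)
        precision = _safe_div(tp, tp + fp)
        sens.append(recall)
        spec.append(_safe_div(tn, tn + fp))
        fscores.append(_safe_div(2 * precision * recall, precision + recall))
    return MetricSet(
        accuracy=float(accuracy),
        sensitivity=float(np.mean(sens)),
        specificity=float(np.mean(spec)),
        f_score=float(np.mean(fscores)),
    )


@dataclass
class MetricReport:
    """Per-fold metrics with mean ± std summaries."""

    per_fold: list[MetricSet]

    @property
    def n_folds(self) -> int:
        return len(self.per_fold)

    def _column(self, name: str) -> np.ndarray:
        return np.array([getattr(m, name) for m in self.per_fold])

    def mean(self, name: str) -> float:
        return float(self._column(name).mean())

    def std(self, name: str) -> float:
        return float(self._column(name).std())  # population std

    def summary(self) -> str:
        lines = [f"Cross-validation report ({self.n_folds} folds)", "-" * 42]
        for name in ("accuracy", "sensitivity", "specificity", "f_score"):
            lines.append(f"{name:<12} {self.mean(name):.4f} ± {self.std(name):.4f}")
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        rows = {
            name: self._column(name)
            for name in ("accuracy", "sensitivity", "specificity", "f_score")
        }
        return pd.DataFrame(rows, index=[f"fold{i + 1}" for i in range(self.n_folds)])


def split_table(table: pd.DataFrame):
    """Split a feature table into (X, y, feature column names)."""
    feature_cols = [c for c in table.columns if c != LABEL_COLUMN]
    X = table[feature_cols].to_numpy(dtype=float)
    y = table[LABEL_COLUMN].to_numpy()
    return X, y, feature_cols


def stratified_folds(y, k: int, seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """Seeded stratified k-fold split; per-class fold sizes differ by ≤ 1."""
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < k:
        raise ValueError(
            f"class {classes[counts.argmin()]!r} has {counts.min()} samples, "
            f"fewer than k={k} folds"
        )
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [(tr, te) for tr, te in splitter.split(np.zeros(len(y)), y)]


def cross_validate(
    classifier_factory: Callable[[np.ndarray, np.ndarray], object],
    table: pd.DataFrame,
    k: int = 10,
    seed: int = 0,
    folds: list[tuple[np.ndarray, np.ndarray]] | None = None,
) -> MetricReport:
    """Stratified k-fold CV of any fit-then-predict classifier.

    ``classifier_factory(X_train, y_train)`` must return an object with a
    ``predict(X)`` method.  Passing precomputed ``folds`` freezes the split
    across compared classifiers.
    """
    X, y, _ = split_table(table)
    class_names = tuple(sorted(np.unique(y).tolist()))
    if folds is None:
        folds = stratified_folds(y, k, seed)
    per_fold = []
    for train_idx, test_idx in folds:
        clf = classifier_factory(X[train_idx], y[train_idx])
        pred = clf.predict(X[test_idx])
        per_fold.append(metrics(confusion(y[test_idx], pred, class_names)))
    return MetricReport(per_fold=per_fold)


def elm_classifier_factory(config: ELMConfig):
    """A cross_validate-compatible factory fitting a fresh ELM per fold."""

    def factory(X_train, y_train):
        return ELM(X_train, y_train, config=config).fit()

    return factory


def activation_sweep(
    table: pd.DataFrame,
    activations: Sequence[str] = ACTIVATION_KINDS,
    elm_config: ELMConfig | None = None,
    k: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """CV accuracy (mean ± std) per activation on one frozen fold split."""
    base = elm_config or ELMConfig()
    _, y, _ = split_table(table)
    folds = stratified_folds(y, k, seed)
    rows = []
    for kind in activations:
        cfg = ELMConfig(
            n_hidden=base.n_hidden,
            activation=kind,
            weight_scale=base.weight_scale,
            ridge=base.ridge,
            seed=base.seed,
        )
        report = cross_validate(elm_classifier_factory(cfg), table, folds=folds)
        rows.append(
            dict(
                activation=kind,
                accuracy_mean=report.mean("accuracy"),
                accuracy_std=report.std("accuracy"),
            )
        )
    return pd.DataFrame(rows)


def validation_curve(
    table: pd.DataFrame,
    hidden_grid: Sequence[int],
    elm_config: ELMConfig | None = None,
    k: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean train and CV accuracy as a function of hidden-unit count."""
    base = elm_config or ELMConfig()
    hidden_grid = list(hidden_grid)
    if hidden_grid != sorted(hidden_grid):
        raise ValueError("hidden_grid must be ascending")
    X, y, _ = split_table(table)
    class_names = tuple(sorted(np.unique(y).tolist()))
    folds = stratified_folds(y, k, seed)
    rows = []
    for H in hidden_grid:
        cfg = ELMConfig(
            n_hidden=H,
            activation=base.activation,
            weight_scale=base.weight_scale,
            ridge=base.ridge,
            seed=base.seed,
        )
        train_acc, val_acc = [], []
        for train_idx, test_idx in folds:
            res = ELM(X[train_idx], y[train_idx], config=cfg).fit()
            train_acc.append(np.mean(res.predict(X[train_idx]) == y[train_idx]))
            pred = res.predict(X[test_idx])
            val_acc.append(metrics(confusion(y[test_idx], pred, class_names)).accuracy)
        rows.append(
            dict(
                n_hidden=H,
                train_accuracy=float(np.mean(train_acc)),
                validation_accuracy=float(np.mean(val_acc)),
            )
        )
    return pd.DataFrame(rows)
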