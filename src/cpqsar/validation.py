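"""Model evaluation: stratified splitting, leave-20%-out CV, accuracy metrics.

Class 2 (carcinogen) is the positive class throughout.  "Leave 20% out"
cross-validation is implemented as stratified 5-fold CV (each fold held out
once); a repeated random-subsampling mode (a random stratified 20% held out
R times) is also provided since the phrase is ambiguous in common usage.
Both the pooled-fold and the fold-averaged accuracy are reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import clone
from sklearn.model_selection import StratifiedKFold, StratifiedShuffleSplit, train_test_split

POSITIVE_CLASS = 2


@dataclass
class EvaluationReport:
    tp: int
    tn: int
    fp: int
    fn: int
    accuracy: float
    sensitivity: float
    specificity: float
    per_fold: list["EvaluationReport"] = field(default_factory=list)
    mean_fold_accuracy: float | None = None

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def evaluate_predictions(y_true: np.ndarray, y_pred: np.ndarray) -> EvaluationReport:
    """Confusion counts and the three headline rates (class 2 = positive)."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) == 0:
        raise ValueError("cannot evaluate an empty dataset")
    tp = int(np.sum((y_true == POSITIVE_CLASS) & (y_pred == POSITIVE_CLASS)))
    tn = int(np.sum((y_true != POSITIVE_CLASS) & (y_pred != POSITIVE_CLASS)))
    fp = int(np.sum((y_true != POSITIVE_CLASS) & (y_pred == POSITIVE_CLASS)))
    fn = int(np.sum((y_true == POSITIVE_CLASS) & (y_pred != POSITIVE_CLASS)))
    n = len(y_true)
    return EvaluationReport(
        tp=tp,
        tn=tn,
        fp=fp,
        fn=fn,
        accuracy=(tp + tn) / n,
        sensitivity=tp / (tp + fn) if tp + fn else 0.0,
        specificity=tn / (tn + fp) if tn + fp else 0.0,
    )


def evaluate(model, X: np.ndarray, y: np.ndarray) -> EvaluationReport:
    """Evaluate a fitted classifier; external sets reuse the model's stored
    normalization upstream (no refit happens here)."""
    return evaluate_predictions(y, model.predict(X))


def stratified_split(
    X: np.ndarray,
    y: np.ndarray,
    test_fraction: float = 0.2,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint, exhaustive stratified train/test index split."""
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must lie in (0, 1)")
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present to stratify")
    idx = np.arange(len(y))
    train_idx, test_idx = train_test_split(
        idx, test_size=test_fraction, stratify=y, random_state=seed
    )
    return train_idx, test_idx


def cross_validate(
    estimator,
    X: np.ndarray,
    y: np.ndarray,
    folds: int = 5,
    seed: int = 0,
    mode: str = "kfold",
    repeats: int = 5,
) -> EvaluationReport:
    """Stratified leave-1/folds-out CV with a fresh model per fold.

    ``mode="kfold"`` (default): the folds partition the data and each is
    held out once; the report pools the confusion counts and also carries
    the per-fold breakdown and fold-averaged accuracy.  ``mode="subsampling"``
    holds a random stratified ``1/folds`` fraction out ``repeats`` times
    (folds no longer partition the data).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if folds < 2:
        raise ValueError("need at least 2 folds")
    _, counts = np.unique(y, return_counts=True)
    if folds > counts.min():
        raise ValueError(f"folds={folds} exceeds the smallest class count {counts.min()}")

    if mode == "kfold":
        splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        splits = splitter.split(X, y)
    elif mode == "subsampling":
        splitter = StratifiedShuffleSplit(
            n_splits=repeats, test_size=1.0 / folds, random_state=seed
        )
        splits = splitter.split(X, y)
    else:
        raise ValueError(f"unknown CV mode {mode!r}")

    y_true_all: list[np.ndarray] = []
    y_pred_all: list[np.ndarray] = []
    per_fold: list[EvaluationReport] = []
    for train_idx, test_idx in splits:
        model = clone(estimator)
        model.fit(X[train_idx], y[train_idx])
        pred = model.predict(X[test_idx])
        per_fold.append(evaluate_predictions(y[test_idx], pred))
        y_true_all.append(y[test_idx])
        y_pred_all.append(pred)
    pooled = evaluate_predictions(np.concatenate(y_true_all), np.concatenate(y_pred_all))
    pooled.per_fold = per_fold
    pooled.mean_fold_accuracy = float(np.mean([r.accuracy for r in per_fold]))
    return pooled
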