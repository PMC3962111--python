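"""Statistical descriptor pre-selection.

Three univariate/bivariate screens in one greedy procedure: descriptors are
ranked by Fisher ratio (between-class squared mean difference over the sum
of within-class variances), walked in decreasing order, and a candidate is
dropped when its absolute Pearson correlation with an already-kept column
exceeds a threshold.  Multicollinearity beyond pairwise correlation is
checked on the kept set via variance-inflation factors (warn-only).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted, validate_data

from .records import DescriptorMatrix

logger = logging.getLogger(__name__)

#: Cap applied when both class variances vanish but the means differ.
FISHER_CAP = 1e12


@dataclass
class SelectionReport:
    kept: list[str]
    dropped: dict[str, str]  # column -> reason
    fisher: dict[str, float]
    correlations: np.ndarray
    column_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        all_cols = set(self.kept) | set(self.dropped)
        if self.column_names and all_cols != set(self.column_names):
            raise ValueError("kept + dropped must cover every column exactly")


def correlation_matrix(m: DescriptorMatrix | np.ndarray) -> np.ndarray:
    """Pearson correlation matrix; constant columns get 0 against all others."""
    X = m.values if isinstance(m, DescriptorMatrix) else np.asarray(m, dtype=float)
    n, p = X.shape
    if n < 3:
        raise ValueError(f"need at least 3 rows for correlations, got {n}")
    constant = X.std(axis=0) == 0
    if constant.any():
        logger.warning("%d constant column(s): correlation set to 0", int(constant.sum()))
    Xs = X.copy()
    # give constant columns unit variance so corrcoef is finite, then zero them
    Xs[:, constant] = np.random.default_rng(0).standard_normal((n, int(constant.sum())))
    C = np.corrcoef(Xs, rowvar=False).reshape(p, p)
    C[constant, :] = 0.0
    C[:, constant] = 0.0
    np.fill_diagonal(C, 1.0)
    return C


def fisher_ratio(col: np.ndarray, labels: np.ndarray) -> float:
    """(mean1 - mean2)^2 / (var1 + var2) with sample (ddof=1) variances."""
    col = np.asarray(col, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError(f"Fisher ratio needs exactly 2 classes, got {len(classes)}")
    a, b = col[labels == classes[0]], col[labels == classes[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each class needs at least 2 members")
    num = (a.mean() - b.mean()) ** 2
    denom = a.var(ddof=1) + b.var(ddof=1)
    if denom == 0.0:
        if num == 0.0:
            return 0.0
        logger.warning("zero within-class variance with distinct means; capping Fisher ratio")
        return FISHER_CAP
    return float(num / denom)


def variance_inflation(X: np.ndarray) -> np.ndarray:
    """VIF of each column against the others (1 for a single column)."""
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if p < 2:
        return np.ones(p)
    out = np.empty(p)
    for j in range(p):
        y = X[:, j]
        others = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
        beta, *_ = np.linalg.lstsq(others, y, rcond=None)
        resid = y - others @ beta
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - float(resid @ resid) / ss_tot if ss_tot > 0 else 0.0
        out[j] = np.inf if r2 >= 1.0 else 1.0 / (1.0 - r2)
    return out


def select_descriptors(
    m: DescriptorMatrix,
    labels: np.ndarray,
    corr_threshold: float = 0.9,
    k: int | None = None,
    vif_warn_threshold: float = 10.0,
) -> SelectionReport:
    """Greedy Fisher-first selection with pairwise-correlation screening.

    Ties in the Fisher ranking are broken by column order.  If fewer than k
    columns survive the correlation screen, all survivors are returned with
    a warning.
    """
    p = m.shape[1]
    k = p if k is None else k
    if k > p:
        raise ValueError(f"k={k} exceeds column count {p}")
    labels = np.asarray(labels)
    C = correlation_matrix(m)
    fisher = {c: fisher_ratio(m.values[:, j], labels) for j, c in enumerate(m.column_names)}
    order = sorted(range(p), key=lambda j: (-fisher[m.column_names[j]], j))

    kept_idx: list[int] = []
    dropped: dict[str, str] = {}
    for j in order:
        name = m.column_names[j]
        if len(kept_idx) >= k:
            dropped[name] = "low_fisher"
            continue
        clash = next((i for i in kept_idx if abs(C[i, j]) > corr_threshold), None)
        if clash is not None:
            dropped[name] = f"correlated_with:{m.column_names[clash]}"
            continue
        kept_idx.append(j)
    if len(kept_idx) < k:
        logger.warning("only %d of requested %d descriptors survived screening", len(kept_idx), k)

    kept_idx_sorted = sorted(kept_idx)
    kept = [m.column_names[j] for j in kept_idx_sorted]
    vif = variance_inflation(m.values[:, kept_idx_sorted])
    for name, v in zip(kept, vif):
        if v > vif_warn_threshold:
            logger.warning("kept descriptor %s has high variance inflation (VIF=%.1f)", name, v)
    return SelectionReport(
        kept=kept,
        dropped=dropped,
        fisher=fisher,
        correlations=C,
        column_names=list(m.column_names),
    )


class FisherCorrelationSelector(TransformerMixin, BaseEstimator):
    """sklearn transformer facade over :func:`select_descriptors`."""

    def __init__(self, corr_threshold: float = 0.9, k: int | None = None):
        self.corr_threshold = corr_threshold
        self.k = k

    def fit(self, X, y):
        X = validate_data(self, X, dtype=float, ensure_all_finite=True)
        names = [f"x{j}" for j in range(X.shape[1])]
        matrix = DescriptorMatrix(X, [f"r{i}" for i in range(len(X))], names)
        self.report_ = select_descriptors(matrix, np.asarray(y), self.corr_threshold, self.k)
        self.support_ = np.array([n in set(self.report_.kept) for n in names])
        return self

    def transform(self, X):
        check_is_fitted(self)
        X = validate_data(self, X, reset=False, dtype=float)
        return X[:, self.support_]

    def get_support(self) -> np.ndarray:
        check_is_fitted(self)
        return self.support_
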