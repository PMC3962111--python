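"""Min-max scaling to [0, 1] with out-of-range clipping.

The Kohonen layer of the CP ANN measures Euclidean distances between input
vectors and weight vectors, so descriptor columns must share a common scale.
Columns are mapped linearly to [0, 1] using the minimum and maximum of the
*fitting* (training) set; values of new data outside the fitted range are
clipped.  Constant columns carry no distance information and map to 0.5.
"""

from __future__ import annotations

import logging

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted, validate_data

from .records import DatasetError, DescriptorMatrix, NormalizationParams

logger = logging.getLogger(__name__)


class MinMaxClipScaler(TransformerMixin, BaseEstimator):
    """Per-column min-max scaler that clips transformed values into [0, 1].

    Unlike :class:`sklearn.preprocessing.MinMaxScaler`, out-of-range values
    of new data are clipped rather than extrapolated (the CP ANN weight-range
    invariant requires inputs in [0, 1]), and constant columns map to 0.5.
    """

    def fit(self, X, y=None):
        X = validate_data(self, X, reset=True, dtype=float, ensure_all_finite=True)
        self.data_min_ = X.min(axis=0)
        self.data_max_ = X.max(axis=0)
        self.constant_mask_ = self.data_max_ == self.data_min_
        if self.constant_mask_.any():
            logger.warning(
                "%d constant column(s) will map to 0.5", int(self.constant_mask_.sum())
            )
        return self

    def transform(self, X):
        check_is_fitted(self)
        X = validate_data(self, X, reset=False, dtype=float, ensure_all_finite=True)
        span = np.where(self.constant_mask_, 1.0, self.data_max_ - self.data_min_)
        out = (X - self.data_min_) / span
        out = np.clip(out, 0.0, 1.0)
        out[:, self.constant_mask_] = 0.5
        return out


def fit_normalization(matrix: DescriptorMatrix) -> NormalizationParams:
    """Fit per-column min/max on a descriptor matrix."""
    scaler = MinMaxClipScaler().fit(matrix.values)
    return NormalizationParams(
        mins=scaler.data_min_,
        maxs=scaler.data_max_,
        column_names=list(matrix.column_names),
        constant=scaler.constant_mask_,
    )


def apply_normalization(matrix: DescriptorMatrix, params: NormalizationParams) -> DescriptorMatrix:
    """Apply fitted params; new data is clipped into [0, 1]."""
    if matrix.shape[1] != params.n_columns:
        raise DatasetError(
            f"column count mismatch: matrix has {matrix.shape[1]}, params {params.n_columns}"
        )
    span = np.where(params.constant, 1.0, params.maxs - params.mins)
    out = np.clip((matrix.values - params.mins) / span, 0.0, 1.0)
    out[:, params.constant] = 0.5
    return DescriptorMatrix(
        values=out,
        row_ids=list(matrix.row_ids),
        column_names=list(matrix.column_names),
        norm=params,
    )
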