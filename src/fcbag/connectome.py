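"""ROI time series -> standardized lower-triangle Pearson connectomes.

The feature vector for a parcellation with R regions is the row-major
lower triangle of the R x R Pearson correlation matrix, i.e.
R(R-1)/2 unique edges (741 for a 39-region parcellation).  The module is
region-count agnostic; atlas identity is metadata only.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "zscore_timeseries",
    "pearson_connectome",
    "vectorize_lower_triangle",
    "devectorize_lower_triangle",
    "edge_labels",
    "cohort_features",
]


def zscore_timeseries(values: np.ndarray, region_labels: list[str] | None = None) -> np.ndarray:
    """Detrend (remove per-column OLS linear trend) then z-score each column.

    Columns are standardized to mean 0 and sample SD 1 (ddof=1).  A column
    whose detrended residual has zero variance is rejected by label.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[0] < 3:
        raise ValueError("need a 2-D array with at least 3 timepoints")
    detrended = signal.detrend(values, axis=0, type="linear")
    sd = detrended.std(axis=0, ddof=1)
    scale = max(1.0, float(np.abs(values).max()))
    bad = np.flatnonzero(sd <= 1e-10 * scale)
    if bad.size:
        labels = [region_labels[i] if region_labels else str(i) for i in bad]
        raise ValueError(f"zero-variance column(s) after detrending: {labels}")
    return (detrended - detrended.mean(axis=0)) / sd


def pearson_connectome(values: np.ndarray) -> np.ndarray:
    """Symmetric R x R Pearson correlation matrix of the columns.

    Expects z-scored input; rejects NaNs.  Diagonal is exactly 1 and
    entries are clipped to [-1, 1] against rounding.
    """
    values = np.asarray(values, dtype=float)
    if np.isnan(values).any():
        raise ValueError("NaN in time-series input")
    corr = np.corrcoef(values, rowvar=False)
    corr = np.clip(corr, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return corr


def edge_labels(region_labels: list[str]) -> list[str]:
    """Row-major lower-triangle edge labels, '<region_i>|<region_j>' with i>j."""
    n = len(region_labels)
    rows, cols = np.tril_indices(n, k=-1)
    return [f"{region_labels[i]}|{region_labels[j]}" for i, j in zip(rows, cols)]


def vectorize_lower_triangle(mat: np.ndarray) -> np.ndarray:
    """Row-major lower triangle (i > j) of a square symmetric matrix."""
    mat = np.asarray(mat, dtype=float)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError("input must be a square matrix")
    rows, cols = np.tril_indices(mat.shape[0], k=-1)
    return mat[rows, cols]


def devectorize_lower_triangle(vec: np.ndarray, diag: float = 1.0) -> np.ndarray:
    """Inverse of :func:`vectorize_lower_triangle`, symmetric output."""
    vec = np.asarray(vec, dtype=float)
    e = vec.size
    n = int(round((1 + np.sqrt(1 + 8 * e)) / 2))
    if n * (n - 1) // 2 != e:
        raise ValueError(f"length {e} is not a triangular number")
    mat = np.full((n, n), diag, dtype=float)
    rows, cols = np.tril_indices(n, k=-1)
    mat[rows, cols] = vec
    mat[cols, rows] = vec
    return mat


def cohort_features(
    timeseries: list[np.ndarray],
    region_labels: list[str],
    subject_ids: list[str],
    fisher_z: bool = False,
) -> pd.DataFrame:
    """Subjects x edges feature table from raw ROI time series.

    Each subject's run is detrended, z-scored, correlated and vectorized.
    With ``fisher_z`` the edges are arctanh-transformed (correlations are
    clipped just inside (-1, 1) first).
    """
    feats = np.empty((len(timeseries), len(region_labels) * (len(region_labels) - 1) // 2))
    for i, ts in enumerate(timeseries):
        std = zscore_timeseries(ts, region_labels)
        feats[i] = vectorize_lower_triangle(pearson_connectome(std))
    if fisher_z:
        feats = np.arctanh(np.clip(feats, -1 + 1e-12, 1 - 1e-12))
    return pd.DataFrame(feats, index=pd.Index(subject_ids, name="subject_id"),
                        columns=edge_labels(region_labels))
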