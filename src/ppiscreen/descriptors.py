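"""Descriptor-matrix preparation: normalization and low-variance filtering.

The QSAR model consumes a compounds x descriptors numeric table (e.g. a
Mold2-style 777-column block).  Preparation is two steps, both of which must
be replayable on unseen compounds with the *training* parameters:

1. min-max normalization of each column to [0, 1] (constant columns map to 0
   and are flagged) — chosen because every downstream distance (fuzzy
   c-means, k-NN, the applicability domain) is Euclidean;
2. removal of columns whose sample variance falls below a threshold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted, validate_data

__all__ = [
    "DescriptorMatrix",
    "DescriptorNormalizer",
    "normalize_columns",
    "low_variance_filter",
    "prepare_matrix",
    "read_descriptor_csv",
    "write_prepared_matrix",
    "read_prepared_matrix",
]


@dataclass
class DescriptorMatrix:
    """Compounds x descriptors table plus its normalization state.

    ``normalization`` is ``"raw"`` or ``"min-max-[0,1]"``; when normalized,
    ``data_min``/``data_max`` hold the per-column training parameters so
    unseen compounds are transformed identically (their transformed values
    may legitimately fall outside [0, 1]).
    """

    values: pd.DataFrame
    normalization: str = "raw"
    data_min: pd.Series | None = field(default=None, repr=False)
    data_max: pd.Series | None = field(default=None, repr=False)
    constant_columns: list[str] = field(default_factory=list)
    removed_columns: list[str] = field(default_factory=list)

    @property
    def compound_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def descriptor_names(self) -> list[str]:
        return list(self.values.columns)


class DescriptorNormalizer(TransformerMixin, BaseEstimator):
    """Min-max scaler to [0, 1] with constant-column zeroing.

    Unlike clipping scalers, transform applies the stored training min/max
    affinely, so out-of-range queries map outside [0, 1] — the applicability
    domain relies on that.  Constant training columns transform to exactly 0.

    Attributes
    ----------
    data_min_, data_max_ : ndarray of shape (n_features,)
    constant_mask_ : boolean ndarray, True where max == min on the training set
    """

    def fit(self, X, y=None):
        X = validate_data(self, X, dtype=float, ensure_all_finite=True)
        self.data_min_ = X.min(axis=0)
        self.data_max_ = X.max(axis=0)
        self.constant_mask_ = self.data_max_ == self.data_min_
        return self

    def transform(self, X):
        check_is_fitted(self)
        X = validate_data(self, X, dtype=float, reset=False)
        span = np.where(self.constant_mask_, 1.0, self.data_max_ - self.data_min_)
        out = (X - self.data_min_) / span
        out[:, self.constant_mask_] = 0.0
        return out

    def inverse_transform(self, X):
        check_is_fitted(self)
        X = np.asarray(X, dtype=float)
        span = np.where(self.constant_mask_, 1.0, self.data_max_ - self.data_min_)
        out = X * span + self.data_min_
        out[:, self.constant_mask_] = np.broadcast_to(
            self.data_min_[self.constant_mask_], out[:, self.constant_mask_].shape
        )
        return out


def _check_numeric(df: pd.DataFrame) -> None:
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            row = bad.index[0] if len(bad) else df.index[0]
            raise ValueError(f"non-numeric value at row {row!r}, column {col!r}")
    if df.isna().any().any():
        col = df.columns[df.isna().any()][0]
        row = df.index[df[col].isna()][0]
        raise ValueError(f"missing value at row {row!r}, column {col!r}")


def normalize_columns(D: DescriptorMatrix) -> DescriptorMatrix:
    """Min-max normalize each column to [0, 1]; constants map to 0.

    Returns a new DescriptorMatrix carrying the per-column min/max so the
    same affine map can be replayed on unseen compounds.
    """
    if D.normalization != "raw":
        raise ValueError("matrix is already normalized")
    _check_numeric(D.values)
    norm = DescriptorNormalizer().fit(D.values.to_numpy(dtype=float))
    vals = pd.DataFrame(norm.transform(D.values.to_numpy(dtype=float)),
                        index=D.values.index, columns=D.values.columns)
    return DescriptorMatrix(
        values=vals,
        normalization="min-max-[0,1]",
        data_min=pd.Series(norm.data_min_, index=D.values.columns),
        data_max=pd.Series(norm.data_max_, index=D.values.columns),
        constant_columns=list(D.values.columns[norm.constant_mask_]),
    )


def low_variance_filter(D: DescriptorMatrix, min_variance: float = 1e-8
                        ) -> tuple[DescriptorMatrix, list[str]]:
    """Drop columns with sample variance below ``min_variance``.

    Variance is measured on the *raw* descriptor scale (recovered from the
    stored normalization span): min-max normalization stretches every
    non-constant column to [0, 1], so a near-constant descriptor would
    otherwise look as variable as any other.  Surviving column order is
    preserved; the removal list is sorted by name.
    """
    if min_variance < 0:
        raise ValueError("min_variance must be >= 0")
    if D.normalization == "raw":
        raise ValueError("normalize before filtering")
    span = (D.data_max - D.data_min) if D.data_min is not None else 1.0
    var = D.values.var(axis=0, ddof=1) * span ** 2
    removed = sorted(var.index[var < min_variance])
    kept = [c for c in D.values.columns if c not in set(removed)]
    out = DescriptorMatrix(
        values=D.values[kept],
        normalization=D.normalization,
        data_min=D.data_min[kept] if D.data_min is not None else None,
        data_max=D.data_max[kept] if D.data_max is not None else None,
        constant_columns=[c for c in D.constant_columns if c in set(kept)],
        removed_columns=removed,
    )
    return out, removed


def prepare_matrix(D: DescriptorMatrix, min_variance: float = 1e-8) -> DescriptorMatrix:
    """Normalize then low-variance filter; the standard preparation."""
    normed = normalize_columns(D)
    prepared, _ = low_variance_filter(normed, min_variance)
    return prepared


def transform_like(D: DescriptorMatrix, query: pd.DataFrame) -> pd.DataFrame:
    """Apply a prepared matrix's normalization to unseen descriptor rows.

    ``query`` must contain every surviving descriptor column (extra columns
    are ignored).  Values outside the training range map outside [0, 1].
    """
    if D.normalization == "raw" or D.data_min is None:
        raise ValueError("matrix carries no normalization parameters")
    missing = [c for c in D.descriptor_names if c not in query.columns]
    if missing:
        raise ValueError(f"query is missing descriptor columns: {missing[:5]}")
    q = query[D.descriptor_names].astype(float)
    span = (D.data_max - D.data_min).replace(0.0, 1.0)
    out = (q - D.data_min) / span
    out[D.constant_columns] = 0.0
    return out


def read_descriptor_csv(path: str) -> DescriptorMatrix:
    """Read a compound x descriptor CSV (header row; first column = id)."""
    df = pd.read_csv(path, index_col=0)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate compound id {dup!r}")
    df.index = df.index.astype(str)
    _check_numeric(df)
    return DescriptorMatrix(values=df.astype(float))


def write_prepared_matrix(D: DescriptorMatrix, csv_path: str, sidecar_path: str) -> None:
    """Write matrix CSV plus a JSON sidecar with normalization parameters."""
    D.values.to_csv(csv_path, index_label="id")
    sidecar = {
        "normalization": D.normalization,
        "data_min": None if D.data_min is None else D.data_min.to_dict(),
        "data_max": None if D.data_max is None else D.data_max.to_dict(),
        "constant_columns": D.constant_columns,
        "removed_columns": D.removed_columns,
    }
    with open(sidecar_path, "w", encoding="utf-8") as fh:
        json.dump(sidecar, fh, indent=1)


def read_prepared_matrix(csv_path: str, sidecar_path: str) -> DescriptorMatrix:
    df = pd.read_csv(csv_path, index_col=0)
    df.index = df.index.astype(str)
    with open(sidecar_path, encoding="utf-8") as fh:
        sc = json.load(fh)
    return DescriptorMatrix(
        values=df.astype(float),
        normalization=sc["normalization"],
        data_min=None if sc["data_min"] is None else pd.Series(sc["data_min"])[df.columns],
        data_max=None if sc["data_max"] is None else pd.Series(sc["data_max"])[df.columns],
        constant_columns=sc["constant_columns"],
        removed_columns=sc["removed_columns"],
    )
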