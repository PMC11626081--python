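"""Containers and preprocessing for paired omics abundance tables.

The pipeline mirrors the conventions used throughout microbiome /
metabolome integration studies: replace zeros in count-scale compositional
tables with a small pseudocount, move to the log scale (where the zero-sum
coefficient constraint makes scores scale-invariant), optionally filter
low-prevalence features and standardize columns, and finally form the
sample cross-covariance that the alternating solvers consume.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "OmicsMatrix",
    "CrossCovariance",
    "replace_zeros",
    "log_transform",
    "standardize",
    "center",
    "prevalence_filter",
    "cross_covariance",
]


@dataclass
class OmicsMatrix:
    """A samples x features numeric table.

    ``compositional=True`` marks tables carrying only relative information
    (e.g. taxon counts or relative abundances), for which only log-ratios
    are interpretable.
    """

    values: np.ndarray
    sample_ids: list = field(default_factory=list)
    feature_ids: list = field(default_factory=list)
    compositional: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D samples x features array")
        n, m = self.values.shape
        if not self.sample_ids:
            self.sample_ids = [f"S{i + 1}" for i in range(n)]
        if not self.feature_ids:
            self.feature_ids = [f"F{j + 1}" for j in range(m)]
        self.sample_ids = list(self.sample_ids)
        self.feature_ids = list(self.feature_ids)
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match row count")
        if len(self.feature_ids) != m:
            raise ValueError("feature_ids length does not match column count")
        if np.isnan(self.values).any():
            raise ValueError("missing values are not supported; filter or drop them first")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, compositional: bool = False) -> "OmicsMatrix":
        return cls(
            values=df.to_numpy(dtype=float),
            sample_ids=[str(s) for s in df.index],
            feature_ids=[str(f) for f in df.columns],
            compositional=compositional,
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.feature_ids)


@dataclass
class CrossCovariance:
    """Sample cross-covariance matrix between two paired tables (q x p)."""

    matrix: np.ndarray
    row_ids: list = field(default_factory=list)
    col_ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be 2-D")
        q, p = self.matrix.shape
        if not self.row_ids:
            self.row_ids = [f"R{j + 1}" for j in range(q)]
        if not self.col_ids:
            self.col_ids = [f"C{j + 1}" for j in range(p)]
        if len(self.row_ids) != q or len(self.col_ids) != p:
            raise ValueError("identifier lengths do not match matrix dimensions")


def replace_zeros(X: OmicsMatrix, value: float = 0.5) -> OmicsMatrix:
    """Replace exact zeros with a positive pseudocount (default 0.5).

    The default 0.5 is on the count scale; for tables already converted to
    relative abundances supply an appropriately small value.
    """
    if not X.compositional:
        raise ValueError("zero replacement applies to compositional tables only")
    if value <= 0:
        raise ValueError("replacement value must be positive")
    if np.any(X.values < 0):
        raise ValueError("counts/abundances cannot be negative")
    out = X.values.copy()
    out[out == 0.0] = value
    return replace(X, values=out)


def log_transform(X: OmicsMatrix) -> OmicsMatrix:
    """Elementwise natural log; requires strictly positive entries."""
    bad = np.argwhere(X.values <= 0)
    if bad.size:
        i, j = bad[0]
        raise ValueError(
            f"nonpositive entry at sample {X.sample_ids[i]!r}, feature "
            f"{X.feature_ids[j]!r}; apply replace_zeros first"
        )
    return replace(X, values=np.log(X.values))


def center(M: OmicsMatrix) -> OmicsMatrix:
    """Column-center (mean 0) without rescaling."""
    return replace(M, values=M.values - M.values.mean(axis=0))


def standardize(M: OmicsMatrix) -> OmicsMatrix:
    """Column-wise zero mean and unit sample variance (n-1 denominator)."""
    if M.n_samples < 2:
        raise ValueError("standardization needs at least 2 samples")
    sd = M.values.std(axis=0, ddof=1)
    zero = np.where(sd == 0)[0]
    if zero.size:
        names = [M.feature_ids[j] for j in zero[:5]]
        raise ValueError(f"zero-variance column(s): {names}; filter them first")
    vals = (M.values - M.values.mean(axis=0)) / sd
    return replace(M, values=vals)


def prevalence_filter(X: OmicsMatrix, min_fraction: float) -> OmicsMatrix:
    """Keep features with nonzero presence in at least ``min_fraction`` of samples.

    Applied to pre-log counts/abundances, e.g. ``min_fraction=0.25`` drops
    taxa seen in fewer than a quarter of the samples.
    """
    if not (0 < min_fraction <= 1):
        raise ValueError("min_fraction must lie in (0, 1]")
    presence = (X.values != 0).mean(axis=0)
    keep = presence >= min_fraction
    if not keep.any():
        raise ValueError("prevalence filter removed all features")
    return replace(
        X,
        values=X.values[:, keep],
        feature_ids=[f for f, k in zip(X.feature_ids, keep) if k],
    )


def cross_covariance(A: OmicsMatrix | np.ndarray, B: OmicsMatrix | np.ndarray) -> CrossCovariance:
    """Sample cross-covariance between the columns of A and B.

    Rows index A's features, columns index B's features; columns are
    centered and the cross-product is scaled by 1/(n-1).  All solver
    outputs are invariant to the positive scaling, since every update
    renormalizes directions to unit l2 norm.
    """
    a_vals = A.values if isinstance(A, OmicsMatrix) else np.asarray(A, dtype=float)
    b_vals = B.values if isinstance(B, OmicsMatrix) else np.asarray(B, dtype=float)
    if a_vals.shape[0] != b_vals.shape[0]:
        raise ValueError("A and B must have the same number of samples")
    if isinstance(A, OmicsMatrix) and isinstance(B, OmicsMatrix):
        if A.sample_ids != B.sample_ids:
            raise ValueError("sample identifiers differ or are ordered differently")
    n = a_vals.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples")
    ac = a_vals - a_vals.mean(axis=0)
    bc = b_vals - b_vals.mean(axis=0)
    mat = ac.T @ bc / (n - 1)
    return CrossCovariance(
        matrix=mat,
        row_ids=list(A.feature_ids) if isinstance(A, OmicsMatrix) else [],
        col_ids=list(B.feature_ids) if isinstance(B, OmicsMatrix) else [],
    )
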