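"""Inter-region correlation features.

For one subject with regional feature matrix F (n_regions x 18), the entry
rho_{l,m} = corr(F[l, :], F[m, :]) measures how similar two white-matter
regions' diffusion profiles are. Only the upper triangle (l < m) carries
information, so a subject is serialized to n*(n-1)/2 pair features — 1128
for the 48-region atlas. Stacking subjects gives the cohort matrix F-hat
(n_subjects x 1128) with a binary diagnosis label per row (1 = case/ASD,
0 = control/TD).

The 18-vectors are correlated raw (no per-column standardization), exactly
as defined; columns with large numeric ranges therefore dominate — see the
package docs. An optional within-subject z-scoring across regions is
available but OFF by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .regional import FEATURE_COLUMNS, RegionTable, SubjectFeatures

__all__ = [
    "PairCorrelationVector",
    "CohortMatrix",
    "pearson",
    "pair_correlation_matrix",
    "upper_triangle_vector",
    "pair_index",
    "pair_from_index",
    "pair_feature_names",
    "assemble_cohort",
    "PairCorrelationTransformer",
]


def n_pairs(n_regions: int) -> int:
    return n_regions * (n_regions - 1) // 2


def pair_index(l: int, m: int, n_regions: int = 48) -> int:
    """0-based position of pair (l, m), 1-based l < m, in lexicographic order.

    For 48 regions: pos(l, m) = (l-1)(96-l)/2 + (m-l) - 1.
    """
    if not (1 <= l < m <= n_regions):
        raise ValueError(f"need 1 <= l < m <= {n_regions}, got ({l}, {m})")
    return (l - 1) * (2 * n_regions - l) // 2 + (m - l) - 1


def pair_from_index(pos: int, n_regions: int = 48) -> tuple[int, int]:
    """Inverse of :func:`pair_index`: the (l, m) pair at a serialized position."""
    if not 0 <= pos < n_pairs(n_regions):
        raise ValueError(f"pair index {pos} out of range for {n_regions} regions")
    l = 1
    offset = pos
    while offset >= n_regions - l:
        offset -= n_regions - l
        l += 1
    return l, l + offset + 1


def pearson(u: np.ndarray, v: np.ndarray) -> tuple[float, bool]:
    """Sample Pearson correlation plus a degeneracy flag.

    If either vector has zero variance the correlation is undefined; the
    policy here returns 0.0 with the flag set, keeping downstream matrices
    finite.
    """
    u = np.asarray(u, dtype=float).ravel()
    v = np.asarray(v, dtype=float).ravel()
    if u.shape != v.shape:
        raise ValueError(f"length mismatch: {u.shape[0]} vs {v.shape[0]}")
    if u.size < 3:
        raise ValueError("need at least 3 observations for a correlation")
    du = u - u.mean()
    dv = v - v.mean()
    denom = np.sqrt(np.dot(du, du) * np.dot(dv, dv))
    if denom == 0.0:
        return 0.0, True
    return float(np.clip(np.dot(du, dv) / denom, -1.0, 1.0)), False


@dataclass
class PairCorrelationVector:
    """Serialized upper triangle of one subject's region-correlation matrix."""

    values: np.ndarray
    n_regions: int
    flagged: np.ndarray  # pairs whose correlation was degenerate (set to 0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.flagged = np.asarray(self.flagged, dtype=bool)
        expect = n_pairs(self.n_regions)
        if self.values.shape != (expect,):
            raise ValueError(f"expected {expect} pair values, got {self.values.shape}")

    def __len__(self) -> int:
        return self.values.shape[0]


def pair_correlation_matrix(
    features: SubjectFeatures | np.ndarray,
    zscore_columns: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """The n_regions x n_regions correlation matrix of a subject's F rows.

    Returns (matrix, flagged) where ``flagged`` marks entries set to 0
    because a row had zero variance or the region was missing. The matrix is
    symmetric with unit diagonal.

    ``zscore_columns`` standardizes each of the 18 columns across regions
    within the subject before correlating (off by default; the raw
    definition is the canonical one).
    """
    if isinstance(features, SubjectFeatures):
        rows = features.values.copy()
        invalid_rows = features.region_missing()
    else:
        rows = np.asarray(features, dtype=float).copy()
        invalid_rows = np.zeros(rows.shape[0], dtype=bool)
    n = rows.shape[0]
    if zscore_columns:
        sd = rows.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        rows = (rows - rows.mean(axis=0)) / sd

    centered = rows - rows.mean(axis=1, keepdims=True)
    ss = np.einsum("ij,ij->i", centered, centered)
    zero_var = ss == 0.0
    invalid = invalid_rows | zero_var

    denom = np.sqrt(np.outer(ss, ss))
    with np.errstate(invalid="ignore", divide="ignore"):
        mat = (centered @ centered.T) / denom
    mat = np.clip(np.nan_to_num(mat, nan=0.0), -1.0, 1.0)
    flagged = np.zeros((n, n), dtype=bool)
    flagged[invalid, :] = True
    flagged[:, invalid] = True
    mat[flagged] = 0.0
    np.fill_diagonal(mat, 1.0)
    np.fill_diagonal(flagged, False)
    return mat, flagged


def upper_triangle_vector(
    matrix: np.ndarray,
    flagged: np.ndarray | None = None,
) -> PairCorrelationVector:
    """Serialize the strict upper triangle in lexicographic (l, m) order."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {matrix.shape}")
    n = matrix.shape[0]
    iu = np.triu_indices(n, k=1)  # row-major == lexicographic (l, m)
    flags = (
        np.zeros(len(iu[0]), dtype=bool)
        if flagged is None
        else np.asarray(flagged, dtype=bool)[iu]
    )
    return PairCorrelationVector(values=matrix[iu].copy(), n_regions=n, flagged=flags)


def pair_feature_names(regions: RegionTable) -> list[str]:
    """Feature names ``pair:<region_l>|<region_m>`` in serialization order."""
    n = len(regions)
    return [
        f"pair:{regions.names[l - 1]}|{regions.names[m - 1]}"
        for l in range(1, n + 1)
        for m in range(l + 1, n + 1)
    ]


@dataclass
class CohortMatrix:
    """Stacked per-subject feature vectors with diagnosis labels.

    ``X`` is (n_subjects, n_features) — 1128 columns for the pair-correlation
    representation of a 48-region atlas, 864 for the flattened summary
    representation. ``y`` holds 1 for cases (ASD) and 0 for controls (TD).
    """

    X: np.ndarray
    y: np.ndarray
    subject_ids: list[str]
    feature_names: list[str]
    representation: str = "corr"
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.ndim != 2:
            raise ValueError("X must be 2D")
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("row count does not match label count")
        if len(self.subject_ids) != self.X.shape[0]:
            raise ValueError("subject id count does not match row count")
        if len(self.feature_names) != self.X.shape[1]:
            raise ValueError("feature-name count does not match column count")
        if not np.isin(self.y, [0, 1]).all():
            raise ValueError("labels must be binary 0/1")

    @property
    def n_subjects(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.X, columns=self.feature_names)
        df.insert(0, "subject_id", self.subject_ids)
        df.insert(1, "label", self.y)
        df.to_csv(path, sep="\t", index=False, float_format="%.12g")

    @classmethod
    def from_tsv(cls, path: str | Path, representation: str = "corr") -> "CohortMatrix":
        df = pd.read_csv(path, sep="\t")
        feature_names = [c for c in df.columns if c not in ("subject_id", "label")]
        return cls(
            X=df[feature_names].to_numpy(dtype=float),
            y=df["label"].to_numpy(dtype=int),
            subject_ids=[str(s) for s in df["subject_id"]],
            feature_names=feature_names,
            representation=representation,
        )


def assemble_cohort(
    vectors: list,
    labels,
    subject_ids: list[str] | None = None,
    feature_names: list[str] | None = None,
    representation: str = "corr",
) -> CohortMatrix:
    """Stack per-subject vectors (PairCorrelationVector or plain arrays) into
    a cohort matrix, checking length consistency per subject."""
    labels = np.asarray(labels, dtype=int)
    if len(vectors) != labels.shape[0]:
        raise ValueError("vector count does not match label count")
    if subject_ids is None:
        subject_ids = [f"sub-{i:04d}" for i in range(len(vectors))]
    rows = []
    width = None
    for sid, vec in zip(subject_ids, vectors):
        arr = vec.values if isinstance(vec, PairCorrelationVector) else np.asarray(vec, dtype=float).ravel()
        if width is None:
            width = arr.shape[0]
        elif arr.shape[0] != width:
            raise ValueError(
                f"subject {sid} has {arr.shape[0]} features, expected {width}"
            )
        rows.append(arr)
    X = np.vstack(rows)
    if feature_names is None:
        feature_names = [f"f{j}" for j in range(X.shape[1])]
    return CohortMatrix(
        X=X,
        y=labels,
        subject_ids=list(subject_ids),
        feature_names=list(feature_names),
        representation=representation,
    )


class PairCorrelationTransformer(BaseEstimator, TransformerMixin):
    """sklearn transformer: per-subject regional matrices -> pair features.

    Accepts X of shape (n_subjects, n_regions, 18) or flattened
    (n_subjects, n_regions*18) and emits (n_subjects, n_regions*(n_regions-1)/2)
    pair-correlation features, composing with sklearn pipelines.

    Parameters
    ----------
    n_regions : int
        Atlas size; used to unflatten 2D input. Default 48.
    zscore_columns : bool
        Standardize the 18 columns across regions within each subject before
        correlating. Default False (the raw definition).
    """

    def __init__(self, n_regions: int = 48, zscore_columns: bool = False):
        self.n_regions = n_regions
        self.zscore_columns = zscore_columns

    def fit(self, X, y=None):
        X = self._validate(X)
        self.n_features_in_ = int(np.prod(X.shape[1:]))
        self.n_output_features_ = n_pairs(self.n_regions)
        return self

    def transform(self, X) -> np.ndarray:
        X = self._validate(X)
        out = np.empty((X.shape[0], n_pairs(self.n_regions)))
        for i, subject in enumerate(X):
            mat, flagged = pair_correlation_matrix(subject, zscore_columns=self.zscore_columns)
            out[i] = upper_triangle_vector(mat, flagged).values
        return out

    def _validate(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            n_cols = len(FEATURE_COLUMNS)
            if X.shape[1] % self.n_regions != 0:
                raise ValueError(
                    f"cannot reshape {X.shape[1]} columns into {self.n_regions} regions"
                )
            X = X.reshape(X.shape[0], self.n_regions, X.shape[1] // self.n_regions)
            if X.shape[2] != n_cols and X.shape[2] < 3:
                raise ValueError("need at least 3 columns per region")
        elif X.ndim != 3:
            raise ValueError("expected (n_subjects, n_regions, n_stats) input")
        return X
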