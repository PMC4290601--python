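"""Two-class expression matrices: loading, validation and normalization.

The central container is :class:`ExpressionMatrix`, a features x samples
numeric table with a binary class label per sample and a record of which
normalizations have been applied.  Matrices are read from plain delimited
text (TSV/CSV) with the sample labels in a separate two-column file, the
layout in which GEO series exports are most commonly redistributed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

NORMALIZATIONS = ("raw", "quantile", "log2", "quantile_log2")


class ExpressionError(ValueError):
    """Raised for malformed expression tables, labels or normalization misuse."""


@dataclass
class ExpressionMatrix:
    """A validated two-class expression matrix (features x samples).

    Parameters
    ----------
    values : pandas.DataFrame
        Numeric matrix with feature ids as index and sample ids as columns.
    labels : pandas.Series
        Class label per sample id; exactly two distinct labels must occur.
    normalization : str
        One of ``raw``, ``quantile``, ``log2``, ``quantile_log2``.
    """

    values: pd.DataFrame
    labels: pd.Series
    normalization: str = "raw"

    def __post_init__(self) -> None:
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        if not isinstance(self.labels, pd.Series):
            self.labels = pd.Series(self.labels)
        if self.normalization not in NORMALIZATIONS:
            raise ExpressionError(
                f"unknown normalization {self.normalization!r}; "
                f"expected one of {NORMALIZATIONS}"
            )
        idx = self.values.index
        cols = self.values.columns
        if idx.duplicated().any():
            dup = idx[idx.duplicated()][0]
            raise ExpressionError(f"duplicate feature id: {dup!r}")
        if cols.duplicated().any():
            dup = cols[cols.duplicated()][0]
            raise ExpressionError(f"duplicate sample id: {dup!r}")
        arr = self.values.to_numpy()
        if arr.size == 0:
            raise ExpressionError("empty expression matrix")
        if not np.issubdtype(arr.dtype, np.number):
            raise ExpressionError("expression matrix contains non-numeric values")
        if not np.isfinite(arr).all():
            bad = np.argwhere(~np.isfinite(arr))[0]
            raise ExpressionError(
                f"non-finite value at feature {idx[bad[0]]!r}, sample {cols[bad[1]]!r}"
            )
        missing = [s for s in cols if s not in self.labels.index]
        if missing:
            raise ExpressionError(f"missing label for sample(s): {missing}")
        self.labels = self.labels.loc[cols]
        classes = sorted(set(self.labels))
        if len(classes) != 2:
            raise ExpressionError(
                f"expected exactly 2 classes, found {len(classes)}: {classes}"
            )

    # -- basic views ---------------------------------------------------
    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def classes(self) -> tuple[str, str]:
        """The two class labels, sorted lexicographically."""
        a, b = sorted(set(self.labels))
        return a, b

    def other_class(self, label: str) -> str:
        a, b = self.classes
        if label == a:
            return b
        if label == b:
            return a
        raise ExpressionError(f"unknown class label {label!r}")

    def class_mask(self, label: str) -> np.ndarray:
        """Boolean mask over samples belonging to ``label``."""
        if label not in self.classes:
            raise ExpressionError(f"unknown class label {label!r}")
        return (self.labels == label).to_numpy()

    def class_size(self, label: str) -> int:
        return int(self.class_mask(label).sum())

    def label_array(self) -> np.ndarray:
        return self.labels.to_numpy()

    def feature_values(self, feature_id: str) -> np.ndarray:
        if feature_id not in self.values.index:
            raise ExpressionError(f"unknown feature {feature_id!r}")
        return self.values.loc[feature_id].to_numpy(dtype=float)

    def subset_features(self, feature_ids) -> "ExpressionMatrix":
        missing = [f for f in feature_ids if f not in self.values.index]
        if missing:
            raise ExpressionError(f"unknown feature(s): {missing}")
        return ExpressionMatrix(
            self.values.loc[list(feature_ids)], self.labels.copy(), self.normalization
        )

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        missing = [s for s in sample_ids if s not in self.values.columns]
        if missing:
            raise ExpressionError(f"unknown sample(s): {missing}")
        return ExpressionMatrix(
            self.values[list(sample_ids)],
            self.labels.loc[list(sample_ids)],
            self.normalization,
        )

    def with_labels(self, labels: pd.Series) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.copy(), labels, self.normalization)


@dataclass(frozen=True)
class ClassPair:
    """Names the positive (disease) and negative (control) roles of the two classes."""

    positive: str
    negative: str

    def __post_init__(self) -> None:
        if self.positive == self.negative:
            raise ExpressionError("positive and negative class must differ")

    @classmethod
    def from_matrix(cls, m: ExpressionMatrix, positive: str) -> "ClassPair":
        if positive not in m.classes:
            raise ExpressionError(
                f"positive class {positive!r} not among matrix classes {m.classes}"
            )
        return cls(positive=positive, negative=m.other_class(positive))


# -- I/O ----------------------------------------------------------------


def _sep_for(path: str, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "," if os.path.splitext(str(path))[1].lower() == ".csv" else "\t"


def read_labels(path, sample_ids=None, sep: str | None = None) -> pd.Series:
    """Read a two-column ``sample_id<sep>label`` table, auto-detecting a header row."""
    raw = pd.read_csv(path, sep=_sep_for(path, sep), header=None, dtype=str)
    if raw.shape[1] < 2:
        raise ExpressionError(
            f"labels file {path} must have two columns (sample_id, label)"
        )
    raw = raw.iloc[:, :2]
    first = str(raw.iloc[0, 0])
    looks_like_header = first.lower() in {"sample", "sample_id", "id", "name"} or (
        sample_ids is not None and first not in set(map(str, sample_ids))
    )
    if looks_like_header and len(raw) > 1:
        raw = raw.iloc[1:]
    labels = pd.Series(raw.iloc[:, 1].values, index=raw.iloc[:, 0].values)
    if labels.index.duplicated().any():
        dup = labels.index[labels.index.duplicated()][0]
        raise ExpressionError(f"duplicate sample id in labels file: {dup!r}")
    return labels


def read_expression_table(
    path,
    labels_path,
    orientation: str = "features_in_rows",
    sep: str | None = None,
    min_class_size: int = 2,
) -> ExpressionMatrix:
    """Load a delimited expression table plus its label file.

    The table must have one header row of ids and one id column (first
    column).  ``orientation`` says whether rows are features or samples;
    the returned matrix is always features x samples.
    """
    if orientation not in ("features_in_rows", "samples_in_rows"):
        raise ExpressionError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep=_sep_for(path, sep), index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    coerced = df.apply(pd.to_numeric, errors="coerce")
    bad = coerced.isna() & ~df.isna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ExpressionError(
            f"non-numeric cell at row {df.index[r]!r}, column {df.columns[c]!r}: "
            f"{df.iat[r, c]!r}"
        )
    if coerced.isna().to_numpy().any():
        r, c = np.argwhere(coerced.isna().to_numpy())[0]
        raise ExpressionError(
            f"blank cell at row {df.index[r]!r}, column {df.columns[c]!r}"
        )
    if orientation == "samples_in_rows":
        coerced = coerced.T
    labels = read_labels(labels_path, sample_ids=coerced.columns, sep=sep)
    m = ExpressionMatrix(coerced, labels, normalization="raw")
    for cls in m.classes:
        if m.class_size(cls) < min_class_size:
            raise ExpressionError(
                f"class {cls!r} has {m.class_size(cls)} sample(s); "
                f"need at least {min_class_size}"
            )
    return m


def write_expression_table(m: ExpressionMatrix, path, labels_path=None, sep=None):
    """Write the matrix (and optionally its labels) back to delimited text."""
    m.values.to_csv(path, sep=_sep_for(path, sep))
    if labels_path is not None:
        m.labels.to_csv(labels_path, sep=_sep_for(labels_path, sep), header=False)


# -- normalization ------------------------------------------------------


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Quantile-normalize samples: every column gets the common per-rank means.

    Tied values within a column receive the mean of the reference values at
    the ranks they jointly occupy (the standard "average" tie dialect).
    """
    if m.normalization != "raw":
        raise ExpressionError(
            f"quantile_normalize expects raw values, got {m.normalization!r}"
        )
    arr = m.values.to_numpy(dtype=float)
    reference = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        col = arr[:, j]
        order = np.argsort(col, kind="stable")
        assigned = np.empty_like(col)
        assigned[order] = reference
        # average reference values over tie groups
        sorted_col = col[order]
        start = 0
        for end in range(1, len(col) + 1):
            if end == len(col) or sorted_col[end] != sorted_col[start]:
                assigned[order[start:end]] = reference[start:end].mean()
                start = end
        out[:, j] = assigned
    values = pd.DataFrame(out, index=m.values.index, columns=m.values.columns)
    return ExpressionMatrix(values, m.labels.copy(), "quantile")


def log2_transform(m: ExpressionMatrix, pseudocount: float = 0.0) -> ExpressionMatrix:
    """Elementwise ``log2(value + pseudocount)``."""
    if pseudocount < 0:
        raise ExpressionError("pseudocount must be >= 0")
    if m.normalization not in ("raw", "quantile"):
        raise ExpressionError(
            f"log2_transform already applied (normalization={m.normalization!r})"
        )
    arr = m.values.to_numpy(dtype=float) + pseudocount
    if (arr <= 0).any():
        r, c = np.argwhere(arr <= 0)[0]
        raise ExpressionError(
            f"non-positive value after pseudocount at feature "
            f"{m.values.index[r]!r}, sample {m.values.columns[c]!r}"
        )
    values = pd.DataFrame(
        np.log2(arr), index=m.values.index, columns=m.values.columns
    )
    norm = "log2" if m.normalization == "raw" else "quantile_log2"
    return ExpressionMatrix(values, m.labels.copy(), norm)
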