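"""Reading and writing feature tables.

Tables are CSV/TSV in either orientation: samples-as-rows (one sample per
line), or features-as-rows as in GEO series-matrix exports. Everything is
converted to the canonical samples-as-rows orientation on read. The label
may live in a named column of the table or in a separate two-column file.
Empty cells and a configurable missing token (default "NA") become
missing values.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import CLASSIFICATION, FeatureMatrix, Outcome
from .errors import DuplicateIdError, ValidationError


@dataclass
class TableDialect:
    delimiter: str = "\t"
    orientation: str = "samples_as_rows"  # or features_as_rows
    label_column: str | None = None       # column of the table holding labels
    missing_token: str = "NA"

    def __post_init__(self):
        if self.orientation not in ("samples_as_rows", "features_as_rows"):
            raise ValidationError(
                f"unknown orientation '{self.orientation}'")


class ParseError(ValidationError):
    def __init__(self, message: str, line: int | None = None):
        self.line = line
        where = f" (line {line})" if line is not None else ""
        super().__init__(message + where)


def _read_frame(path, dialect: TableDialect) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"file not found: {path}")
    try:
        df = pd.read_csv(path, sep=dialect.delimiter, index_col=0,
                         na_values=[dialect.missing_token],
                         keep_default_na=False)
    except pd.errors.ParserError as e:
        line = getattr(e, "lineno", None)
        raise ParseError(f"cannot parse {path}: {e}", line) from e
    if df.index.has_duplicates:
        dups = sorted(set(df.index[df.index.duplicated()].astype(str)))
        raise DuplicateIdError(f"duplicate row ids in {path}: {dups}")
    if df.columns.has_duplicates:
        dups = sorted(set(df.columns[df.columns.duplicated()].astype(str)))
        raise DuplicateIdError(f"duplicate column ids in {path}: {dups}")
    return df


def read_feature_table(path, dialect: TableDialect | None = None,
                       task: str = CLASSIFICATION,
                       labels_path=None):
    """Read a feature table (and labels) into canonical orientation.

    Labels come either from ``dialect.label_column`` (a column of the
    samples-as-rows view) or from ``labels_path``, a two-column
    id-to-label file. Returns ``(FeatureMatrix, Outcome | None)``.
    """
    dialect = dialect or TableDialect()
    df = _read_frame(path, dialect)
    if dialect.orientation == "features_as_rows":
        df = df.T

    y = None
    if dialect.label_column is not None:
        if dialect.label_column not in df.columns:
            raise ParseError(
                f"label column '{dialect.label_column}' absent from {path}")
        raw = df[dialect.label_column]
        df = df.drop(columns=[dialect.label_column])
        y = _make_outcome(raw.to_numpy(), task)
    elif labels_path is not None:
        lab = _read_labels(labels_path, dialect)
        missing = [s for s in df.index.astype(str) if s not in lab]
        if missing:
            raise ParseError(
                f"labels file lacks samples: {missing[:5]}"
                + ("..." if len(missing) > 5 else ""))
        y = _make_outcome(
            np.asarray([lab[s] for s in df.index.astype(str)]), task)

    try:
        values = df.apply(pd.to_numeric, errors="raise").to_numpy(dtype=float)
    except (ValueError, TypeError) as e:
        raise ParseError(f"non-numeric cell in {path}: {e}") from e
    X = FeatureMatrix(values, list(df.index.astype(str)),
                      list(df.columns.astype(str)))
    return X, y


def _read_labels(path, dialect: TableDialect) -> dict[str, str]:
    df = pd.read_csv(path, sep=dialect.delimiter, header=0, dtype=str)
    if df.shape[1] < 2:
        raise ParseError(f"labels file {path} needs two columns (id, label)")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def _make_outcome(raw: np.ndarray, task: str) -> Outcome:
    if task == CLASSIFICATION:
        # numeric 0/1 codes in files are read as categories
        labels = [str(v) for v in raw]
        labels = [lab[:-2] if lab.endswith(".0") else lab for lab in labels]
        return Outcome(CLASSIFICATION, labels)
    return Outcome("regression", np.asarray(raw, dtype=float))


def write_feature_table(X: FeatureMatrix, path,
                        y: Outcome | None = None,
                        dialect: TableDialect | None = None) -> None:
    """Write a matrix (and optional labels as a trailing column) to disk."""
    dialect = dialect or TableDialect()
    df = X.to_frame()
    if y is not None:
        col = dialect.label_column or "label"
        df[col] = list(y.values)
    if dialect.orientation == "features_as_rows":
        if y is not None:
            raise ValidationError(
                "labels column not representable features-as-rows; "
                "write labels to a separate file")
        df = df.T
    df.to_csv(path, sep=dialect.delimiter, na_rep=dialect.missing_token,
              index_label="id")


def write_labels(y: Outcome, sample_ids: list[str], path,
                 delimiter: str = "\t") -> None:
    pd.DataFrame({"id": sample_ids, "label": list(y.values)}).to_csv(
        path, sep=delimiter, index=False)
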