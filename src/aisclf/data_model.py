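"""Tabular data container shared by every stage of the pipeline.

A :class:`FeatureTable` is a plain samples-by-features matrix of floats with
per-column type tags, optional binary class labels (1 = recurrent,
0 = non-recurrent in the clinical setting this package targets), and a
per-row incompleteness flag set at load time.  Nominal clinical codes are
stored as non-negative integer codes and, by default, enter distance
computations as ordinary real values; the distance-based methods downstream
(fuzzy c-means, ant k-means, the immune classifier) all operate on the
min-max normalized unit cube, which is what makes their fixed radii (0.1)
scale-meaningful.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

FEATURE_KINDS = ("continuous", "binary", "ordinal", "nominal")

TARGET_KIND = "target"


class ConfigurationError(ValueError):
    """A schema or config entry does not match the data."""


class EmptyTableError(ValueError):
    """An operation produced or received a table with no rows."""


@dataclass
class FeatureTable:
    """Samples x features matrix with typing, names and optional labels.

    Parameters
    ----------
    values
        Float matrix, rows are samples ("antigens"), columns features.
    feature_names
        One label per column.
    feature_kinds
        Per-column tag from ``FEATURE_KINDS``.
    labels
        Optional per-row class in {0, 1}.
    incomplete
        Optional boolean mask marking rows that contained unparseable or
        missing cells at load time.  ``None`` means "no missingness info";
        such tables are treated as complete.
    """

    values: np.ndarray
    feature_names: list[str]
    feature_kinds: list[str]
    labels: np.ndarray | None = None
    incomplete: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        n, d = self.values.shape
        if len(self.feature_names) != d or len(self.feature_kinds) != d:
            raise ValueError("feature_names/feature_kinds length must match columns")
        for kind in self.feature_kinds:
            if kind not in FEATURE_KINDS:
                raise ValueError(f"unknown feature kind {kind!r}")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape != (n,):
                raise ValueError("labels length must equal number of rows")
        if self.incomplete is not None:
            self.incomplete = np.asarray(self.incomplete, dtype=bool)
            if self.incomplete.shape != (n,):
                raise ValueError("incomplete mask length must equal number of rows")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def copy(self) -> "FeatureTable":
        return FeatureTable(
            self.values.copy(),
            list(self.feature_names),
            list(self.feature_kinds),
            None if self.labels is None else self.labels.copy(),
            None if self.incomplete is None else self.incomplete.copy(),
        )

    def select_rows(self, idx: np.ndarray) -> "FeatureTable":
        idx = np.asarray(idx)
        return FeatureTable(
            self.values[idx],
            list(self.feature_names),
            list(self.feature_kinds),
            None if self.labels is None else self.labels[idx],
            None if self.incomplete is None else self.incomplete[idx],
        )

    def select_features(self, idx: Sequence[int]) -> "FeatureTable":
        """Column subset by 0-based indices; labels and masks are kept."""
        idx = list(idx)
        return FeatureTable(
            self.values[:, idx],
            [self.feature_names[i] for i in idx],
            [self.feature_kinds[i] for i in idx],
            self.labels,
            self.incomplete,
        )


@dataclass
class NormalizationParams:
    """Per-feature min and max for the [0, 1] min-max map.

    Constant columns (max == min) are mapped to 0 and inverted back to their
    constant value, so transform followed by inverse is the identity.
    """

    minimum: np.ndarray
    maximum: np.ndarray

    def __post_init__(self) -> None:
        self.minimum = np.asarray(self.minimum, dtype=float)
        self.maximum = np.asarray(self.maximum, dtype=float)
        if np.any(self.maximum < self.minimum):
            raise ValueError("per-feature max must be >= min")

    @property
    def span(self) -> np.ndarray:
        return self.maximum - self.minimum

    def apply(self, values: np.ndarray, clip: bool = True) -> np.ndarray:
        """Map raw values onto the unit cube fitted on training data.

        Unseen samples may fall outside the training range; ``clip`` keeps
        them inside [0, 1], which the radius-based classifiers require.
        """
        values = np.asarray(values, dtype=float)
        span = np.where(self.span > 0, self.span, 1.0)
        out = (values - self.minimum) / span
        out[:, self.span == 0] = 0.0
        if clip:
            out = np.clip(out, 0.0, 1.0)
        return out

    def invert(self, normalized: np.ndarray) -> np.ndarray:
        normalized = np.asarray(normalized, dtype=float)
        return normalized * self.span + self.minimum


def load_cohort_csv(path: str | Path, schema: Mapping[str, str]) -> FeatureTable:
    """Read a cohort CSV into a :class:`FeatureTable`.

    ``schema`` maps column names to a kind from ``FEATURE_KINDS`` or
    ``"target"`` for the class column.  Rows with blank or unparseable cells
    are flagged incomplete, not dropped — cleaning is a separate explicit
    step (:func:`drop_incomplete_records`).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    target_cols = [c for c, k in schema.items() if k == TARGET_KIND]
    if len(target_cols) != 1:
        raise ConfigurationError("schema must name exactly one target column")
    target_col = target_cols[0]
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    for col in schema:
        if col not in df.columns:
            raise ConfigurationError(f"schema column {col!r} not found in CSV header")

    feature_names = [c for c in df.columns if c in schema and c != target_col]
    feature_kinds = [schema[c] for c in feature_names]
    numeric = df[feature_names].apply(lambda s: pd.to_numeric(s, errors="coerce"))
    target = pd.to_numeric(df[target_col], errors="coerce")
    incomplete = numeric.isna().any(axis=1).to_numpy() | target.isna().to_numpy()
    labels = np.where(target.fillna(0).to_numpy() != 0, 1, 0)
    values = numeric.to_numpy(dtype=float)
    values = np.nan_to_num(values, nan=0.0)  # placeholder; rows stay flagged
    return FeatureTable(values, feature_names, feature_kinds, labels, incomplete)


def write_cohort_csv(table: FeatureTable, path: str | Path, target_column: str = "recurrence") -> None:
    """Write a labeled table as a UTF-8 CSV with a header row.

    Values are printed with 12 significant digits so a write/read round trip
    preserves them to that precision; labels round-trip exactly.
    """
    if table.labels is None:
        raise ValueError("table must be labeled to be exported as a cohort CSV")
    df = pd.DataFrame(table.values, columns=table.feature_names)
    df[target_column] = table.labels
    df.to_csv(path, index=False, float_format="%.12g")


def schema_for(table: FeatureTable, target_column: str = "recurrence") -> dict[str, str]:
    """Schema dict that reloads a CSV written by :func:`write_cohort_csv`."""
    schema = dict(zip(table.feature_names, table.feature_kinds))
    schema[target_column] = TARGET_KIND
    return schema


def drop_incomplete_records(table: FeatureTable) -> FeatureTable:
    """Remove rows flagged incomplete; surviving row order is preserved."""
    if table.incomplete is None:
        return table.copy()
    keep = np.flatnonzero(~table.incomplete)
    if keep.size == 0:
        raise EmptyTableError("every record is incomplete")
    out = table.select_rows(keep)
    out.incomplete = np.zeros(keep.size, dtype=bool)
    return out


def one_hot_expand(table: FeatureTable) -> FeatureTable:
    """Expand nominal columns into 0/1 indicator columns.

    Integer-coded nominal variables otherwise enter distance computations
    as ordinal reals; this switch provides the one-hot representation for
    sensitivity analysis.  Continuous, binary and ordinal columns pass
    through unchanged; each nominal column ``f`` becomes columns
    ``f=<code>`` for every observed code.
    """
    cols, names, kinds = [], [], []
    for j, kind in enumerate(table.feature_kinds):
        col = table.values[:, j]
        if kind == "nominal":
            for code in np.unique(col):
                cols.append((col == code).astype(float))
                names.append(f"{table.feature_names[j]}={int(code)}")
                kinds.append("binary")
        else:
            cols.append(col)
            names.append(table.feature_names[j])
            kinds.append(kind)
    return FeatureTable(
        np.column_stack(cols), names, kinds, table.labels, table.incomplete
    )


def normalize_minmax(table: FeatureTable) -> tuple[FeatureTable, NormalizationParams]:
    """Map every column to [0, 1]; constant columns map to 0.

    Returns the transformed table and the fitted parameters, which are
    reused (``params.apply``) to place unseen samples on the same scale.
    """
    if table.n_samples == 0:
        raise EmptyTableError("cannot normalize an empty table")
    params = NormalizationParams(table.values.min(axis=0), table.values.max(axis=0))
    out = table.copy()
    out.values = params.apply(table.values, clip=False)
    return out, params
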