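"""Feature-table container and delimited-text / ARFF readers and writers.

A :class:`FeatureTable` is the package's in-memory representation of a
classification dataset: an ``n_instances x n_features`` numeric matrix, a
unique string identifier per feature, and one categorical class label per
instance.  Tables are read from CSV (header row mandatory, label column
named or last) or ARFF; missing values and non-numeric feature cells are
hard errors at load time, since the selection algorithm has no missing-data
semantics.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import arff as scipy_arff

logger = logging.getLogger("fsbrr")

__all__ = ["FeatureTable", "read_table", "write_table", "write_ground_truth"]


@dataclass
class FeatureTable:
    """Instances x features matrix plus a categorical class vector.

    Invariants enforced at construction: feature identifiers are unique,
    values are finite floats of shape ``(n_instances, n_features)``, and the
    class vector has at least two distinct labels.
    """

    values: np.ndarray
    feature_ids: list[str]
    class_labels: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.class_labels = np.asarray(self.class_labels)
        n, m = self.values.shape
        if m != len(self.feature_ids):
            raise ValueError(
                f"{len(self.feature_ids)} feature ids for {m} columns"
            )
        if n != len(self.class_labels):
            raise ValueError(
                f"{len(self.class_labels)} class labels for {n} instances"
            )
        if len(set(self.feature_ids)) != len(self.feature_ids):
            dupes = sorted(
                f for f in set(self.feature_ids) if self.feature_ids.count(f) > 1
            )
            raise ValueError(f"duplicate feature ids: {dupes}")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))
            cells = [
                f"(row {r}, feature {self.feature_ids[c]})" for r, c in bad[:10]
            ]
            raise ValueError(f"missing or non-finite values at {', '.join(cells)}")
        if len(np.unique(self.class_labels)) < 2:
            raise ValueError("class vector must contain at least 2 distinct labels")

    @property
    def n_instances(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def subset_features(self, ids: list[str]) -> "FeatureTable":
        """Return a new table restricted to ``ids`` (kept in the given order)."""
        index = {f: k for k, f in enumerate(self.feature_ids)}
        missing = [f for f in ids if f not in index]
        if missing:
            raise KeyError(f"unknown feature ids: {missing}")
        cols = [index[f] for f in ids]
        return FeatureTable(self.values[:, cols], list(ids), self.class_labels.copy())

    def subset_instances(self, rows: np.ndarray) -> "FeatureTable":
        """Return a new table restricted to the given row indices."""
        return FeatureTable(
            self.values[rows, :], list(self.feature_ids), self.class_labels[rows]
        )

    def to_dataframe(self, label_name: str = "class") -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_ids)
        df[label_name] = self.class_labels
        return df


def _table_from_dataframe(df: pd.DataFrame, label_column: str) -> FeatureTable:
    if label_column == "last":
        label_column = df.columns[-1]
    if label_column not in df.columns:
        raise ValueError(f"label column {label_column!r} not present")
    labels = df[label_column].astype(str).to_numpy()
    features = df.drop(columns=[label_column])

    # Locate missing cells before numeric coercion so the error names them.
    na = features.isna()
    if na.to_numpy().any():
        cols = list(features.columns)
        cells = [
            f"(row {r}, column {cols[c]})"
            for r, c in zip(*np.nonzero(na.to_numpy()))
        ]
        raise ValueError(f"missing values at {', '.join(cells[:10])}")
    coerced = features.apply(pd.to_numeric, errors="coerce")
    bad = coerced.isna().to_numpy()
    if bad.any():
        cols = list(features.columns)
        cells = [f"(row {r}, column {cols[c]})" for r, c in zip(*np.nonzero(bad))]
        raise ValueError(f"non-numeric feature cells at {', '.join(cells[:10])}")
    table = FeatureTable(
        coerced.to_numpy(dtype=float), [str(c) for c in features.columns], labels
    )
    logger.info(
        "loaded table: %d instances, %d features, %d classes",
        table.n_instances,
        table.n_features,
        len(np.unique(labels)),
    )
    return table


def read_table(
    path: str | Path,
    format: str | None = None,
    label_column: str = "last",
) -> FeatureTable:
    """Read a feature table from CSV or ARFF.

    Parameters
    ----------
    path
        Input file.  When ``format`` is None it is inferred from the
        extension (``.arff`` -> ARFF, anything else -> CSV).
    format
        ``"csv"`` or ``"arff"``.
    label_column
        Name of the class column, or ``"last"`` for the final column.
    """
    path = Path(path)
    if format is None:
        format = "arff" if path.suffix.lower() == ".arff" else "csv"
    if format == "csv":
        with open(path, newline="") as fh:
            header = next(csv.reader(fh))
        if len(set(header)) != len(header):
            dupes = sorted(h for h in set(header) if header.count(h) > 1)
            raise ValueError(f"duplicate feature ids in header: {dupes}")
        df = pd.read_csv(path)
    elif format == "arff":
        data, meta = scipy_arff.loadarff(str(path))
        df = pd.DataFrame(data)
        for col in df.columns:  # nominal attributes arrive as bytes
            if df[col].dtype == object:
                df[col] = df[col].str.decode("utf-8")
    else:
        raise ValueError(f"unknown format {format!r}")
    return _table_from_dataframe(df, label_column)


def write_table(
    table: FeatureTable, path: str | Path, label_name: str = "class"
) -> None:
    """Write the table as CSV with the class column last."""
    table.to_dataframe(label_name).to_csv(path, index=False)


def write_ground_truth(truth: dict, path: str | Path) -> None:
    """Write a sidecar JSON of per-feature ground-truth group membership."""
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
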