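"""Tabular dataset container, standardization, and file plumbing.

The whole pipeline operates on small numeric tables with a categorical
class column.  :class:`TabularDataset` keeps, next to the value matrix,
the bookkeeping the error-control machinery relies on: per-column
provenance (``original`` vs ``engineered`` permuted controls), the
mapping from each original variable to its engineered counterpart, and
per-row provenance (``original`` vs ``generated``) so that augmentation
is always reversible.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("esomaug")

#: column provenance tags
ORIGINAL = "original"
ENGINEERED = "engineered"
#: row provenance tags
ROW_ORIGINAL = "original"
ROW_GENERATED = "generated"

#: name of the row-provenance column in CSV outputs
ORIGIN_COLUMN = "__origin"


class ValidationError(ValueError):
    """Raised when a dataset violates its invariants."""


@dataclass
class TabularDataset:
    """An n x J numeric feature table with class labels.

    Parameters
    ----------
    values
        Feature matrix of shape ``(n, J)``; must be finite.
    labels
        Length-``n`` class vector (any hashable dtype).
    feature_names
        Length-``J`` unique identifiers.
    provenance
        Per-column tag, ``original`` or ``engineered``.
    counterpart_map
        Maps each original column name to its engineered (permuted)
        counterpart, when controls are present.
    row_origin
        Per-row tag, ``original`` or ``generated``.
    """

    values: np.ndarray
    labels: np.ndarray
    feature_names: list[str]
    provenance: np.ndarray = None  # type: ignore[assignment]
    counterpart_map: dict[str, str] = field(default_factory=dict)
    row_origin: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D array")
        self.labels = np.asarray(self.labels)
        self.feature_names = [str(f) for f in self.feature_names]
        if self.provenance is None:
            self.provenance = np.array([ORIGINAL] * self.n_features, dtype=object)
        else:
            self.provenance = np.asarray(self.provenance, dtype=object)
        if self.row_origin is None:
            self.row_origin = np.array([ROW_ORIGINAL] * self.n_rows, dtype=object)
        else:
            self.row_origin = np.asarray(self.row_origin, dtype=object)
        self.validate()

    # -- shape accessors -------------------------------------------------
    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.labels)

    def validate(self) -> "TabularDataset":
        if self.n_rows < 2:
            raise ValidationError("dataset needs at least 2 rows")
        if self.n_features < 1:
            raise ValidationError("dataset needs at least 1 feature")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))
            r, c = bad[0]
            raise ValidationError(
                f"non-finite value at row {int(r)}, column "
                f"'{self.feature_names[int(c)]}' ({len(bad)} offending cells)"
            )
        if len(self.labels) != self.n_rows:
            raise ValidationError("labels length does not match row count")
        if len(self.feature_names) != self.n_features:
            raise ValidationError("feature_names length does not match column count")
        if len(set(self.feature_names)) != self.n_features:
            raise ValidationError("feature names must be unique")
        if len(self.provenance) != self.n_features:
            raise ValidationError("provenance length does not match column count")
        if len(self.row_origin) != self.n_rows:
            raise ValidationError("row_origin length does not match row count")
        engineered = [f for f, p in zip(self.feature_names, self.provenance) if p == ENGINEERED]
        mapped = list(self.counterpart_map.values())
        if sorted(engineered) != sorted(mapped):
            raise ValidationError(
                "every engineered column must appear exactly once in counterpart_map"
            )
        if len(mapped) != len(set(mapped)):
            raise ValidationError("counterpart_map values must be unique")
        for orig in self.counterpart_map:
            if orig not in self.feature_names:
                raise ValidationError(f"counterpart_map key '{orig}' is not a column")
        return self

    def require_classes(self, k: int = 2) -> None:
        if len(self.classes) < k:
            raise ValidationError(f"at least {k} distinct classes required")

    # -- views -----------------------------------------------------------
    def original_feature_names(self) -> list[str]:
        return [f for f, p in zip(self.feature_names, self.provenance) if p == ORIGINAL]

    def engineered_feature_names(self) -> list[str]:
        return [f for f, p in zip(self.feature_names, self.provenance) if p == ENGINEERED]

    def column_index(self, name: str) -> int:
        return self.feature_names.index(name)

    def original_only(self) -> "TabularDataset":
        """Drop engineered columns (used for the final generation pass)."""
        keep = [i for i, p in enumerate(self.provenance) if p == ORIGINAL]
        return TabularDataset(
            values=self.values[:, keep],
            labels=self.labels.copy(),
            feature_names=[self.feature_names[i] for i in keep],
            provenance=self.provenance[keep],
            counterpart_map={},
            row_origin=self.row_origin.copy(),
        )

    def original_rows(self) -> "TabularDataset":
        """Drop generated rows, restoring the pre-augmentation table."""
        keep = self.row_origin == ROW_ORIGINAL
        return TabularDataset(
            values=self.values[keep],
            labels=self.labels[keep],
            feature_names=list(self.feature_names),
            provenance=self.provenance.copy(),
            counterpart_map=dict(self.counterpart_map),
            row_origin=self.row_origin[keep],
        )

    def copy(self) -> "TabularDataset":
        return TabularDataset(
            values=self.values.copy(),
            labels=self.labels.copy(),
            feature_names=list(self.feature_names),
            provenance=self.provenance.copy(),
            counterpart_map=dict(self.counterpart_map),
            row_origin=self.row_origin.copy(),
        )

    # -- pandas bridges --------------------------------------------------
    def to_frame(self, target_column: str = "Class", origin_column: str | None = ORIGIN_COLUMN) -> pd.DataFrame:
        frame = pd.DataFrame(self.values, columns=self.feature_names)
        frame[target_column] = self.labels
        if origin_column:
            frame[origin_column] = self.row_origin
        return frame


@dataclass
class Scaler:
    """Per-column z-standardization; constant columns get unit scale."""

    means: np.ndarray
    sds: np.ndarray

    @classmethod
    def fit(cls, values: np.ndarray) -> "Scaler":
        values = np.asarray(values, dtype=float)
        means = values.mean(axis=0)
        sds = values.std(axis=0, ddof=0)
        sds = np.where(sds > 0, sds, 1.0)
        return cls(means=means, sds=sds)

    @classmethod
    def identity(cls, n_features: int) -> "Scaler":
        return cls(means=np.zeros(n_features), sds=np.ones(n_features))

    def transform(self, values: np.ndarray) -> np.ndarray:
        return (np.asarray(values, dtype=float) - self.means) / self.sds

    def inverse(self, values: np.ndarray) -> np.ndarray:
        return np.asarray(values, dtype=float) * self.sds + self.means


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def read_dataset(
    path: str,
    target_column: str = "Class",
    delimiter: str = ",",
    on_missing: str = "error",
) -> TabularDataset:
    """Read a delimited text file into a :class:`TabularDataset`.

    Feature columns are coerced to numeric.  Missing cells raise an
    error naming their coordinates by default; with ``on_missing="drop"``
    the affected rows are removed and their count logged.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    frame = pd.read_csv(path, delimiter=delimiter)
    if target_column not in frame.columns:
        raise ValidationError(f"target column '{target_column}' not found in {path}")
    labels = frame[target_column].to_numpy()
    feature_frame = frame.drop(columns=[target_column])
    origin = None
    if ORIGIN_COLUMN in feature_frame.columns:
        origin = feature_frame[ORIGIN_COLUMN].to_numpy()
        feature_frame = feature_frame.drop(columns=[ORIGIN_COLUMN])
    coerced = feature_frame.apply(pd.to_numeric, errors="coerce")
    newly_bad = coerced.isna() & ~feature_frame.isna()
    if newly_bad.to_numpy().any():
        r, c = np.argwhere(newly_bad.to_numpy())[0]
        raise ValidationError(
            f"non-numeric value at row {int(r)}, column '{feature_frame.columns[int(c)]}'"
        )
    missing = coerced.isna()
    if missing.to_numpy().any():
        if on_missing == "drop":
            keep = ~missing.any(axis=1)
            n_dropped = int((~keep).sum())
            logger.warning("dropped %d rows with missing values from %s", n_dropped, path)
            coerced = coerced[keep]
            labels = labels[keep.to_numpy()]
            if origin is not None:
                origin = origin[keep.to_numpy()]
        else:
            r, c = np.argwhere(missing.to_numpy())[0]
            raise ValidationError(
                f"missing value at row {int(r)}, column '{coerced.columns[int(c)]}'"
            )
    return TabularDataset(
        values=coerced.to_numpy(dtype=float),
        labels=labels,
        feature_names=list(coerced.columns),
        row_origin=origin,
    )


def write_dataset(
    data: TabularDataset,
    path: str,
    target_column: str = "Class",
    delimiter: str = ",",
) -> str:
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    frame = data.to_frame(target_column=target_column)
    frame.to_csv(path, sep=delimiter, index=False, float_format="%.17g")
    return path


# ---------------------------------------------------------------------------
# run report
# ---------------------------------------------------------------------------

def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


@dataclass
class RunReport:
    """Machine-readable record of a full safe-augmentation run.

    Round-trips losslessly through JSON (numpy scalars are converted on
    construction).
    """

    payload: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.payload = _jsonable(self.payload)

    def __getitem__(self, key):
        return self.payload[key]

    def __contains__(self, key) -> bool:
        return key in self.payload

    def update(self, **entries) -> None:
        self.payload.update(_jsonable(entries))

    def to_json(self, path: str | None = None) -> str:
        text = json.dumps(self.payload, indent=2, sort_keys=True)
        if path is not None:
            os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
            with open(path, "w") as handle:
                handle.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, text_or_path: str) -> "RunReport":
        if os.path.exists(text_or_path):
            with open(text_or_path) as handle:
                return cls(payload=json.load(handle))
        return cls(payload=json.loads(text_or_path))


def write_outputs(
    data: TabularDataset,
    report: RunReport,
    out_prefix: str,
    target_column: str = "Class",
    delimiter: str = ",",
    profile=None,
) -> dict[str, str]:
    """Write the augmented CSV, the JSON report, and (optionally) the
    selection-profile CSV under a common path prefix."""
    parent = os.path.dirname(os.path.abspath(out_prefix))
    os.makedirs(parent, exist_ok=True)
    paths = {}
    paths["data"] = write_dataset(
        data, out_prefix + "_augmented.csv", target_column=target_column, delimiter=delimiter
    )
    report.to_json(out_prefix + "_report.json")
    paths["report"] = out_prefix + "_report.json"
    if profile is not None:
        frame = profile.to_frame()
        frame.to_csv(out_prefix + "_selection.csv", sep=delimiter, index=False)
        paths["profile"] = out_prefix + "_selection.csv"
    return paths
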