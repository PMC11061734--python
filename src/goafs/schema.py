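"""Clinical-table schema and delimited-text I/O.

The package works on the standard 14-attribute processed heart-disease
layout: 13 predictors (Age, Sex, CP, Trestbps, Chol, Fbs, Restecg,
Thalach, Exang, OldPeak, Slope, Ca, Thal) plus a binary disease-status
target ``Num``.  Files are delimited text with a configurable
missing-value token (``"?"`` by convention).

Feature indices are 1-based in all user-facing reports, in the schema
order above, so the subset ``{2, 3, 7}`` names Sex, CP and Restecg.
Internally everything is 0-based.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "ParseError",
    "FeatureDescriptor",
    "FeatureSchema",
    "Dataset",
    "cleveland_schema",
    "read_table",
    "write_table",
    "summarize",
    "missingness_report",
]


class SchemaError(ValueError):
    """A value violates the feature schema (range / category set)."""


class ParseError(ValueError):
    """A delimited file could not be parsed into the expected layout."""


@dataclass(frozen=True)
class FeatureDescriptor:
    """One predictor column: its kind, admissible values and units.

    ``kind`` is ``"numeric"`` (finite ``bounds``) or ``"nominal"``
    (finite ``categories`` of integer codes).
    """

    name: str
    kind: str
    bounds: tuple[float, float] | None = None
    categories: tuple[int, ...] | None = None
    unit: str = ""
    description: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("numeric", "nominal"):
            raise SchemaError(f"{self.name}: kind must be numeric or nominal")
        if self.kind == "numeric":
            if self.bounds is None or not all(math.isfinite(b) for b in self.bounds):
                raise SchemaError(f"{self.name}: numeric feature needs finite bounds")
            if self.bounds[0] > self.bounds[1]:
                raise SchemaError(f"{self.name}: empty bounds interval")
        else:
            if not self.categories:
                raise SchemaError(f"{self.name}: nominal feature needs a category set")

    def contains(self, value: float) -> bool:
        if self.kind == "numeric":
            lo, hi = self.bounds  # type: ignore[misc]
            return lo <= value <= hi
        return value in self.categories  # type: ignore[operator]


@dataclass(frozen=True)
class FeatureSchema:
    """Ordered 13-predictor schema plus a binary target column."""

    features: tuple[FeatureDescriptor, ...]
    target: str = "Num"
    positive_label: int = 1

    def __post_init__(self) -> None:
        if len(self.features) != 13:
            raise SchemaError(f"expected 13 predictor descriptors, got {len(self.features)}")
        names = [f.name for f in self.features]
        if len(set(names)) != len(names):
            raise SchemaError("duplicate feature names")

    @property
    def n_features(self) -> int:
        return len(self.features)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(f.name for f in self.features)

    def index(self, name: str) -> int:
        """0-based column index of a feature name."""
        try:
            return self.names.index(name)
        except ValueError:
            raise SchemaError(f"unknown feature {name!r}") from None

    def resolve(self, indices_1based: Iterable[int]) -> tuple[str, ...]:
        """Map 1-based feature indices to names (reporting convention)."""
        out = []
        for i in indices_1based:
            if not 1 <= i <= self.n_features:
                raise SchemaError(f"feature index {i} outside 1..{self.n_features}")
            out.append(self.features[i - 1].name)
        return tuple(out)


def cleveland_schema() -> FeatureSchema:
    """The standard processed heart-disease schema.

    Kinds follow the imputation-rule split used throughout the package:
    mean-imputed columns are numeric, mode-imputed columns are nominal
    with explicit integer category codes.  Numeric bounds are generous
    physiological validation ranges, not observed data ranges.
    """
    f = FeatureDescriptor
    return FeatureSchema(
        features=(
            f("Age", "numeric", bounds=(1.0, 120.0), unit="year"),
            f("Sex", "nominal", categories=(0, 1), description="0 female, 1 male"),
            f("CP", "nominal", categories=(1, 2, 3, 4), description="chest pain type"),
            f("Trestbps", "numeric", bounds=(50.0, 300.0), unit="mm Hg",
              description="resting blood pressure"),
            f("Chol", "numeric", bounds=(50.0, 700.0), unit="mg/dl",
              description="serum cholesterol"),
            f("Fbs", "numeric", bounds=(0.0, 1.0),
              description="fasting blood sugar > 120 mg/dl"),
            f("Restecg", "nominal", categories=(0, 1, 2),
              description="resting electrocardiography"),
            f("Thalach", "numeric", bounds=(1.0, 300.0), unit="bpm",
              description="maximum heart rate"),
            f("Exang", "nominal", categories=(0, 1),
              description="exercise-induced angina"),
            f("OldPeak", "numeric", bounds=(0.0, 10.0),
              description="exercise-induced ST depression"),
            f("Slope", "nominal", categories=(1, 2, 3),
              description="slope of peak exercise ST segment"),
            f("Ca", "nominal", categories=(0, 1, 2, 3),
              description="number of major vessels coloured"),
            f("Thal", "nominal", categories=(3, 6, 7),
              description="thalassemia status"),
        )
    )


@dataclass
class Dataset:
    """A validated clinical table: values, missingness mask and labels.

    ``values`` is an ``(n, 13)`` float array (nominal categories stored
    as their integer codes); ``missing`` is a same-shape boolean mask;
    masked cells carry no information.  ``labels`` are binary {0, 1} and
    never missing.
    """

    values: np.ndarray
    missing: np.ndarray
    labels: np.ndarray
    schema: FeatureSchema = field(default_factory=cleveland_schema)
    provenance: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.missing = np.asarray(self.missing, dtype=bool)
        self.labels = np.asarray(self.labels, dtype=int)
        n, d = self.values.shape
        if n < 1:
            raise SchemaError("dataset must have at least one row")
        if d != self.schema.n_features:
            raise SchemaError(f"expected {self.schema.n_features} columns, got {d}")
        if self.missing.shape != self.values.shape:
            raise SchemaError("missing mask shape does not match values")
        if self.labels.shape != (n,):
            raise SchemaError("labels length does not match row count")
        if not np.isin(self.labels, (0, 1)).all():
            raise SchemaError("labels must be binary {0,1} with no missing entries")
        self._validate_ranges()

    def _validate_ranges(self) -> None:
        for j, desc in enumerate(self.schema.features):
            col = self.values[:, j]
            obs = ~self.missing[:, j]
            bad = [i for i in np.flatnonzero(obs) if not desc.contains(col[i])]
            if bad:
                raise SchemaError(
                    f"feature {desc.name} (index {j + 1}): value {col[bad[0]]!r} "
                    f"out of range at row {bad[0] + 1}"
                    + (f" (and {len(bad) - 1} more rows)" if len(bad) > 1 else "")
                )

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def n_missing(self) -> int:
        return int(self.missing.sum())

    def copy(self) -> "Dataset":
        return Dataset(
            values=self.values.copy(),
            missing=self.missing.copy(),
            labels=self.labels.copy(),
            schema=self.schema,
            provenance=self.provenance,
        )

    def to_frame(self) -> pd.DataFrame:
        """Values (NaN where missing) plus the target column."""
        vals = self.values.copy()
        vals[self.missing] = np.nan
        df = pd.DataFrame(vals, columns=list(self.schema.names))
        df[self.schema.target] = self.labels
        return df


def _looks_like_header(row: Sequence[str], missing_token: str) -> bool:
    for cell in row:
        cell = cell.strip()
        if cell == missing_token:
            return False
        try:
            float(cell)
            return False
        except ValueError:
            continue
    return True


def read_table(
    path: str | Path,
    missing_token: str = "?",
    schema: FeatureSchema | None = None,
    delimiter: str = ",",
    binarize_target: bool = True,
) -> Dataset:
    """Read a 14-column delimited text file into a validated :class:`Dataset`.

    Cells equal to ``missing_token`` become masked entries.  The target
    column may not be missing.  With ``binarize_target`` (default) any
    raw target value > 0 maps to label 1, matching the convention for
    the 0–4 disease-severity encoding of the source archive; with it
    off, targets must already be 0/1.
    """
    schema = schema or cleveland_schema()
    d = schema.n_features
    rows: list[list[str]] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter=delimiter)
        for lineno, row in enumerate(reader, start=1):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) != d + 1:
                raise ParseError(
                    f"{path}: line {lineno}: expected {d + 1} columns, got {len(row)}"
                )
            rows.append([c.strip() for c in row])
    if rows and _looks_like_header(rows[0], missing_token):
        rows = rows[1:]
    if not rows:
        raise ParseError(f"{path}: no data rows")

    n = len(rows)
    values = np.zeros((n, d))
    missing = np.zeros((n, d), dtype=bool)
    labels = np.zeros(n, dtype=int)
    for i, row in enumerate(rows):
        for j, cell in enumerate(row[:d]):
            if cell == missing_token:
                missing[i, j] = True
                continue
            try:
                values[i, j] = float(cell)
            except ValueError:
                raise ParseError(
                    f"{path}: row {i + 1}, feature {schema.features[j].name}: "
                    f"cannot parse {cell!r}"
                ) from None
        tcell = row[d]
        if tcell == missing_token:
            raise ParseError(f"{path}: row {i + 1}: target value is missing")
        try:
            raw = float(tcell)
        except ValueError:
            raise ParseError(
                f"{path}: row {i + 1}: cannot parse target {tcell!r}"
            ) from None
        if binarize_target:
            labels[i] = 1 if raw > 0 else 0
        else:
            if raw not in (0.0, 1.0):
                raise ParseError(
                    f"{path}: row {i + 1}: target {raw} is not binary "
                    "(enable binarize_target for raw severity codes)"
                )
            labels[i] = int(raw)
    return Dataset(values=values, missing=missing, labels=labels, schema=schema,
                   provenance=str(path))


def write_table(
    dataset: Dataset,
    path: str | Path,
    missing_token: str = "?",
    delimiter: str = ",",
    header: bool = True,
) -> None:
    """Write a dataset back to delimited text; round-trips bit-exactly."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        if header:
            writer.writerow(list(dataset.schema.names) + [dataset.schema.target])
        for i in range(dataset.n):
            row = [
                missing_token if dataset.missing[i, j] else repr(float(dataset.values[i, j]))
                for j in range(dataset.schema.n_features)
            ]
            row.append(str(int(dataset.labels[i])))
            writer.writerow(row)


def summarize(dataset: Dataset) -> pd.DataFrame:
    """Per-feature min / max / mean / std over non-missing cells.

    Std uses the sample (n − 1) convention.  A feature with no observed
    cell (or a single cell, for std) reports NaN — an explicit undefined
    marker, never zero.
    """
    records = []
    for j, desc in enumerate(dataset.schema.features):
        col = dataset.values[~dataset.missing[:, j], j]
        if col.size == 0:
            mn = mx = mean = std = float("nan")
        else:
            mn, mx, mean = float(col.min()), float(col.max()), float(col.mean())
            std = float(col.std(ddof=1)) if col.size > 1 else float("nan")
        records.append(
            {"index": j + 1, "feature": desc.name, "min": mn, "max": mx,
             "mean": mean, "std": std}
        )
    df = pd.DataFrame.from_records(records)
    df.attrs["std_convention"] = "sample (ddof=1)"
    return df


def missingness_report(dataset: Dataset) -> pd.DataFrame:
    """Per-feature missing count / %, distinct and unique value counts.

    ``distinct`` counts different observed values; ``unique`` counts
    values observed exactly once.
    """
    records = []
    n = dataset.n
    for j, desc in enumerate(dataset.schema.features):
        obs = dataset.values[~dataset.missing[:, j], j]
        miss = int(dataset.missing[:, j].sum())
        vals, counts = np.unique(obs, return_counts=True)
        records.append(
            {
                "index": j + 1,
                "feature": desc.name,
                "missing": miss,
                "missing_pct": 100.0 * miss / n,
                "distinct": int(vals.size),
                "unique": int((counts == 1).sum()),
            }
        )
    return pd.DataFrame.from_records(records)


def report_to_json(df: pd.DataFrame, path: str | Path) -> None:
    """Serialize a report DataFrame as a stable JSON document."""
    payload = json.loads(df.to_json(orient="records"))
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
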