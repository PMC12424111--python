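"""Cohort tables on disk: CSV with a JSON sidecar schema.

The sidecar (``<name>.csv.schema.json``) records column names, dtypes,
and which columns are required, so a reader can validate a file without
guessing.  Missing external-measure values are empty CSV cells (NaN in
memory); the round trip is lossless including the missingness mask.
Columns not in the schema are preserved in a passthrough area and
reported with a warning, never silently dropped or coerced.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .simulator import MEASURE_NAMES, CohortTable

REQUIRED_COLUMNS = (
    "id", "age", "education", "gender", "ethnicity",
    "k1", "k2", "k3", "k4", "k5", "k6",
)
SCORE_COLUMNS = tuple(f"accuracy_k{i}" for i in range(1, 7))


class CohortSchemaError(ValueError):
    """The file does not conform to the documented cohort schema."""


def _schema_path(path: Path) -> Path:
    return path.with_name(path.name + ".schema.json")


def write_cohort(table: CohortTable, path: str | Path) -> Path:
    """Write a cohort as CSV plus its sidecar schema."""
    path = Path(path)
    df = table.data
    df.to_csv(path, index=False)
    schema = {
        "columns": {c: str(df[c].dtype) for c in df.columns},
        "required": list(REQUIRED_COLUMNS),
        "n_rows": int(len(df)),
    }
    _schema_path(path).write_text(json.dumps(schema, indent=2) + "\n",
                                  encoding="utf-8")
    return path


def read_cohort(path: str | Path) -> CohortTable:
    """Read and validate a cohort CSV.

    Raises CohortSchemaError for an empty file or missing required
    columns (all violations enumerated in the message); warns about
    extra columns, which are kept as-is.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise CohortSchemaError(f"{path}: empty file, not a cohort table") from None
    if len(df) == 0:
        raise CohortSchemaError(f"{path}: cohort table has no rows")
    problems = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if problems:
        raise CohortSchemaError(
            f"{path}: missing required columns: {', '.join(problems)}")
    known = set(REQUIRED_COLUMNS) | set(SCORE_COLUMNS) | set(MEASURE_NAMES)
    extra = [c for c in df.columns if c not in known]
    if extra:
        warnings.warn(
            f"{path}: extra columns preserved as passthrough: {', '.join(extra)}",
            stacklevel=2,
        )
    for c in ("k1", "k2", "k3", "k4", "k5", "k6"):
        if not pd.api.types.is_numeric_dtype(df[c]):
            raise CohortSchemaError(f"{path}: column {c!r} must be numeric")
    return CohortTable(df)
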