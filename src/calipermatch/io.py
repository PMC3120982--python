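"""Cohort table input/output and schema validation.

Cohorts are rectangular CSV tables (comma-separated, header row, UTF-8,
"." decimal, empty field = missing) with one binary treatment column, one
outcome column, and covariate columns. Binary covariates must be pre-coded
0/1; rows with missing values in any declared column are dropped
(complete-case analysis) with the exclusion count logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("calipermatch")

__all__ = ["CohortSchema", "SchemaError", "read_cohort", "write_cohort"]


class SchemaError(ValueError):
    """Cohort table does not conform to its declared schema."""


@dataclass
class CohortSchema:
    """Declared roles and kinds of a cohort table's columns."""

    treatment_column: str
    outcome_column: str
    outcome_kind: str  # "binary" | "continuous"
    covariate_columns: dict = field(default_factory=dict)  # name -> "binary"|"continuous"

    def __post_init__(self):
        if self.outcome_kind not in ("binary", "continuous"):
            raise SchemaError("outcome_kind must be 'binary' or 'continuous'")
        bad = {k for k in self.covariate_columns.values()} - {"binary", "continuous"}
        if bad:
            raise SchemaError(f"unknown covariate kinds: {sorted(bad)}")

    @property
    def columns(self) -> list:
        return [self.treatment_column, self.outcome_column, *self.covariate_columns]


def _check_binary(series: pd.Series, name: str):
    vals = set(pd.unique(series.dropna()))
    if not vals <= {0, 1, 0.0, 1.0}:
        raise SchemaError(
            f"column {name!r} must contain only 0/1, found {sorted(vals)[:5]}"
        )


def read_cohort(path, schema: CohortSchema) -> pd.DataFrame:
    """Read and validate a cohort CSV; complete-case filter on the schema's
    columns. Returns only the declared columns, typed float."""
    df = pd.read_csv(path)
    missing = [c for c in schema.columns if c not in df.columns]
    if missing:
        raise SchemaError(f"missing columns in {path}: {missing}")
    df = df[schema.columns]
    n0 = len(df)
    df = df.dropna()
    n_excluded = n0 - len(df)
    if n_excluded:
        logger.info("excluded %d of %d rows with missing values", n_excluded, n0)
    if df.empty:
        raise SchemaError("no complete-case rows remain")
    _check_binary(df[schema.treatment_column], schema.treatment_column)
    if schema.outcome_kind == "binary":
        _check_binary(df[schema.outcome_column], schema.outcome_column)
    for name, kind in schema.covariate_columns.items():
        if kind == "binary":
            _check_binary(df[name], name)
    z = df[schema.treatment_column]
    if z.nunique() < 2:
        raise SchemaError("one treatment arm is empty after filtering")
    return df.astype(float).reset_index(drop=True)


def write_cohort(df: pd.DataFrame, path) -> None:
    """Write a cohort table in the package's CSV dialect."""
    df.to_csv(path, index=False, na_rep="")
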