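"""Readers/writers for the package's TSV dialects and JSON configs.

All tables are UTF-8, tab-delimited, one header row, decimal point, no
thousands separators.  ``read_table`` validates against a named schema
and reports the offending row and column on failure.
"""
from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["SCHEMAS", "SchemaError", "read_table", "write_table", "file_digest"]

# column -> kind: str | int | float | nonneg_int | nonneg_float
SCHEMAS = {
    "plate_counts": {
        "mouse_id": "str",
        "host": "str",
        "day": "nonneg_float",
        "category": "str",
        "count": "nonneg_int",
        "depth": "nonneg_int",
    },
    "markers": {
        "mouse_id": "str",
        "host": "str",
        "day": "nonneg_float",
        "yfp": "nonneg_int",
        "cfp": "nonneg_int",
    },
    "competition": {
        "mouse_id": "str",
        "host": "str",
        "housing": "str",
        "time_h": "nonneg_float",
        "mutant": "nonneg_int",
        "reference": "nonneg_int",
    },
    "resistance": {
        "mouse_id": "str",
        "host": "str",
        "day": "nonneg_float",
        "antibiotic": "str",
        "resistant": "nonneg_int",
        "total": "nonneg_int",
        "dilution_r": "float",
        "dilution_t": "float",
    },
    "growth_curves": {
        "medium": "str",
        "time_h": "nonneg_float",
        "od": "float",
    },
    "hybridization": {
        "sample": "str",
        "replicate": "nonneg_int",
        "median_fluorescence": "float",
    },
    "calibration": {
        "sample": "str",
        "rate": "float",
        "replicate": "nonneg_int",
        "fluorescence": "float",
    },
    "phenotype": {
        "mouse_id": "str",
        "host": "str",
        "day": "nonneg_float",
        "gat_neg": "nonneg_int",
        "total": "nonneg_int",
    },
    "clone_typing": {
        "mouse_id": "str",
        "clone": "str",
        "locus": "str",
        "state": "str",
    },
    "variants": {
        "population": "str",
        "host": "str",
        "target": "str",
        "class": "str",
        "frequency": "nonneg_float",
    },
    "trajectories": {
        "mouse_id": "str",
        "host": "str",
        "day": "nonneg_float",
        "category": "str",
        "frequency": "float",
    },
}

_NUMERIC = {"int", "float", "nonneg_int", "nonneg_float"}


class SchemaError(ValueError):
    pass


def read_table(path, schema: str) -> pd.DataFrame:
    """Read and validate a TSV against a named schema.

    Errors name the schema, 1-based data row and column.  An empty file
    with a valid header yields an empty frame with a warning.
    """
    spec = _get_schema(schema)
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in spec if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing column(s) {missing} for schema {schema!r}")
    if df.empty:
        warnings.warn(f"{path.name}: empty table (header only)", stacklevel=2)
    out = {}
    for col, kind in spec.items():
        series = df[col]
        if kind == "str":
            out[col] = series.astype(str)
            continue
        vals = pd.to_numeric(series, errors="coerce")
        bad = vals.isna() & series.notna()
        if bad.any():
            row = int(np.argmax(bad.to_numpy())) + 1
            raise SchemaError(
                f"{path.name}: non-numeric value {series[bad].iloc[0]!r} "
                f"in column {col!r} at data row {row}"
            )
        if series.isna().any():
            row = int(np.argmax(series.isna().to_numpy())) + 1
            raise SchemaError(f"{path.name}: missing value in column {col!r} at data row {row}")
        if kind.startswith("nonneg") and (vals < 0).any():
            row = int(np.argmax((vals < 0).to_numpy())) + 1
            raise SchemaError(
                f"{path.name}: negative value in column {col!r} at data row {row}"
            )
        if kind.endswith("int"):
            if not np.allclose(vals, np.round(vals)):
                row = int(np.argmax(~np.isclose(vals, np.round(vals)).to_numpy())) + 1
                raise SchemaError(
                    f"{path.name}: non-integer value in column {col!r} at data row {row}"
                )
            out[col] = vals.astype(int)
        else:
            out[col] = vals.astype(float)
    return pd.DataFrame(out)[list(spec.keys())]


def write_table(df: pd.DataFrame, path, schema: str) -> None:
    """Write a TSV in schema column order."""
    spec = _get_schema(schema)
    missing = [c for c in spec if c not in df.columns]
    if missing:
        raise SchemaError(f"cannot write schema {schema!r}: missing column(s) {missing}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df[list(spec.keys())].to_csv(path, sep="\t", index=False)


def _get_schema(schema: str) -> dict:
    try:
        return SCHEMAS[schema]
    except KeyError:
        raise SchemaError(f"unknown schema {schema!r}; known: {sorted(SCHEMAS)}") from None


def file_digest(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def config_digest(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()
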