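"""Reading and writing the per-site TSV table set.

Files: patients.tsv, diagnoses.tsv, medications.tsv, labs.tsv,
hierarchy.tsv (+ truth.tsv and code_map.tsv when generated).  Everything is
plain tab-separated text so a site directory is portable and diffable.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import EmrTables, SimTruth

_SCHEMAS: dict[str, dict[str, str]] = {
    "patients": {
        "patient_id": "str", "sex": "str", "birth_year": "int", "race": "str",
        "death_status": "str", "n_encounters": "int", "span_years": "float",
    },
    "diagnoses": {"patient_id": "str", "code": "str", "date": "str"},
    "medications": {"patient_id": "str", "order_string": "str", "date": "str"},
    "labs": {"patient_id": "str", "test_name": "str", "value": "float", "date": "str"},
    "hierarchy": {"code": "str", "level": "str", "name": "str", "parent": "str"},
}


class SchemaError(ValueError):
    """A table violates its schema; the message names table, row and column."""


def write_tables(tables: EmrTables, directory) -> list[Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for name in _SCHEMAS:
        path = directory / f"{name}.tsv"
        getattr(tables, name).to_csv(path, sep="\t", index=False)
        written.append(path)
    return written


def write_truth(truth: SimTruth, directory) -> Path:
    path = Path(directory) / "truth.tsv"
    truth.to_frame().to_csv(path, sep="\t", index=False)
    return path


def write_code_map(code_map: dict[str, str], directory, level: str = "full_name") -> Path:
    path = Path(directory) / "code_map.tsv"
    pd.DataFrame(
        {"source_code": list(code_map), "target_code": list(code_map.values()),
         "level": level}
    ).to_csv(path, sep="\t", index=False)
    return path


def read_code_map(path) -> dict[str, str]:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("source_code", "target_code"):
        if col not in frame.columns:
            raise SchemaError(f"code_map: missing column {col!r}")
    return dict(zip(frame["source_code"], frame["target_code"]))


def _coerce(frame: pd.DataFrame, table: str) -> pd.DataFrame:
    schema = _SCHEMAS[table]
    missing = [c for c in schema if c not in frame.columns]
    if missing:
        raise SchemaError(f"{table}: missing column {missing[0]!r}")
    out = {}
    for col, kind in schema.items():
        series = frame[col]
        if kind in ("int", "float"):
            coerced = pd.to_numeric(series, errors="coerce")
            bad = coerced.isna() & series.notna()
            if kind == "float":
                bad |= ~np.isfinite(coerced.fillna(0.0))
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise SchemaError(
                    f"{table}: non-numeric value in column {col!r} at row {row}: "
                    f"{series.iloc[row]!r}")
            if coerced.isna().any():
                row = int(np.flatnonzero(coerced.isna().to_numpy())[0])
                raise SchemaError(f"{table}: missing value in column {col!r} at row {row}")
            out[col] = coerced.astype(np.int64) if kind == "int" else coerced.astype(float)
        else:
            out[col] = series.fillna("").astype(str)
    return pd.DataFrame(out)


def read_tables(directory) -> EmrTables:
    """Read a site directory back into :class:`EmrTables`.

    Round-trips ``write_tables`` output field-for-field.  A malformed file
    raises :class:`SchemaError` naming the table, row and column.
    """
    directory = Path(directory)
    if not (directory / "patients.tsv").exists():
        raise SchemaError("patients table required")
    frames = {}
    for name in _SCHEMAS:
        path = directory / f"{name}.tsv"
        if not path.exists():
            if name == "hierarchy":
                frames[name] = pd.DataFrame(columns=list(_SCHEMAS[name]))
                continue
            raise SchemaError(f"{name} table required")
        raw = pd.read_csv(path, sep="\t", dtype=str)
        frames[name] = _coerce(raw, name)
    tables = EmrTables(**frames)
    _check_referential(tables)
    return tables


def _check_referential(tables: EmrTables) -> None:
    known = set(tables.patients["patient_id"])
    for name in ("diagnoses", "medications", "labs"):
        frame = getattr(tables, name)
        if frame.empty:
            continue
        orphan = ~frame["patient_id"].isin(known)
        if orphan.any():
            row = int(np.flatnonzero(orphan.to_numpy())[0])
            raise SchemaError(
                f"{name}: patient_id {frame['patient_id'].iloc[row]!r} at row {row} "
                "not present in patients table")
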