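"""Readers and writers for the package's tidy CSV dialects.

Influx tables use the fixed header ``n_source,S_mM,replicate,
v_umol_per_gDW_h``; metabolite tables use ``treatment,organ,replicate,
analyte,concentration``.  Decimal separator is always '.', independent of
locale.  Readers are strict: a missing column is a schema error naming the
column, a non-numeric or empty cell is a parse error naming the line — no
value is ever silently coerced to zero or NA.  Provenance travels in a JSON
sidecar next to the CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .errors import ParseError, SchemaError
from .simulate import (
    INFLUX_COLUMNS,
    METABOLITE_COLUMNS,
    InfluxDataset,
    MetaboliteTable,
)

__all__ = [
    "read_influx_csv",
    "write_influx_csv",
    "read_metabolite_csv",
    "write_metabolite_csv",
    "provenance_path",
    "write_json",
]


def provenance_path(csv_path: str | Path) -> Path:
    """Sidecar JSON path for a CSV: ``<name>.provenance.json``."""
    p = Path(csv_path)
    return p.with_suffix(p.suffix + ".provenance.json")


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def _read_strict(path: str | Path, columns: list[str],
                 numeric: list[str]) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing required column(s) {missing}; "
            f"found {list(df.columns)}")
    for col in numeric:
        conv = pd.to_numeric(df[col].str.strip(), errors="coerce")
        bad = conv.isna()
        if bad.any():
            # +2: 1-based lines plus the header row
            lines = [int(i) + 2 for i in df.index[bad][:5]]
            raise ParseError(
                f"{path}: non-numeric value(s) in column {col!r} at "
                f"line(s) {lines}")
        df[col] = conv
    # replicate ids are ints when they look like ints, strings otherwise
    rep = pd.to_numeric(df["replicate"], errors="coerce")
    if len(df) and rep.notna().all() and (rep == rep.round()).all():
        df["replicate"] = rep.astype(int)
    return df[columns]


def _load_provenance(csv_path: str | Path) -> dict:
    sidecar = provenance_path(csv_path)
    if sidecar.exists():
        return json.loads(sidecar.read_text())
    return {"source": str(csv_path)}


def read_influx_csv(path: str | Path) -> InfluxDataset:
    """Read an influx table; header must match the declared dialect exactly."""
    df = _read_strict(path, INFLUX_COLUMNS, ["S_mM", "v_umol_per_gDW_h"])
    return InfluxDataset(data=df, provenance=_load_provenance(path))


def write_influx_csv(dataset: InfluxDataset, path: str | Path) -> None:
    """Write an influx table plus its provenance sidecar."""
    dataset.data.to_csv(path, index=False)
    write_json(dataset.provenance, provenance_path(path))


def read_metabolite_csv(path: str | Path) -> MetaboliteTable:
    """Read a metabolite table; header must match the declared dialect."""
    df = _read_strict(path, METABOLITE_COLUMNS, ["concentration"])
    return MetaboliteTable(data=df, provenance=_load_provenance(path))


def write_metabolite_csv(table: MetaboliteTable, path: str | Path) -> None:
    """Write a metabolite table plus its provenance sidecar."""
    table.data.to_csv(path, index=False)
    write_json(table.provenance, provenance_path(path))
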