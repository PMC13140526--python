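"""Delimited-text tables with explicit units and validation.

Every table the pipeline writes is plain CSV preceded by a comment header
block that records the format version and one unit line per column:

    # colhtl-table v1
    # unit: pre = g
    # unit: post = g
    participant,treatment,period,outcome,pre,post
    P01,INCO,1,hbmass_g,912.1,950.3

Readers validate the header against a declared schema (column names, units,
and plausibility ranges) and report malformed rows with their line numbers,
so a haematocrit recorded in percent never silently enters a
fraction-typed column.
"""

from __future__ import annotations

import io as _io
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ColumnSpec",
    "TableSchema",
    "TableValidationError",
    "CROSSOVER_SCHEMA",
    "REBREATHING_SCHEMA",
    "write_table",
    "read_table",
]

MAGIC = "# colhtl-table v1"


class TableValidationError(ValueError):
    """A table failed schema validation; message lists offending lines."""


@dataclass(frozen=True)
class ColumnSpec:
    name: str
    unit: str
    dtype: str = "float"  # "float" | "int" | "str"
    lo: float | None = None
    hi: float | None = None


@dataclass(frozen=True)
class TableSchema:
    name: str
    columns: tuple[ColumnSpec, ...]

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.columns)

    @property
    def units(self) -> dict[str, str]:
        return {c.name: c.unit for c in self.columns}


CROSSOVER_SCHEMA = TableSchema(
    "crossover",
    (
        ColumnSpec("participant", "label", "str"),
        ColumnSpec("treatment", "label", "str"),
        ColumnSpec("period", "1|2", "int", 1, 2),
        ColumnSpec("outcome", "label", "str"),
        ColumnSpec("pre", "outcome units", "float"),
        ColumnSpec("post", "outcome units", "float"),
    ),
)

REBREATHING_SCHEMA = TableSchema(
    "rebreathing",
    (
        ColumnSpec("participant", "label", "str"),
        ColumnSpec("method", "2min|6min", "str"),
        ColumnSpec("co_administered", "mL", "float", 0.0, 500.0),
        ColumnSpec("co_unabsorbed", "mL", "float", 0.0, 500.0),
        ColumnSpec("cohb_pre", "%", "float", 0.0, 100.0),
        ColumnSpec("cohb_post", "%", "float", 0.0, 100.0),
        ColumnSpec("hb_conc", "g/L", "float", 50.0, 250.0),
        ColumnSpec("hct", "fraction", "float", 0.30, 0.60),
        ColumnSpec("body_mass", "kg", "float", 30.0, 200.0),
    ),
)


def write_table(df: pd.DataFrame, path: str | Path, schema: TableSchema) -> None:
    """Write a CSV with the colhtl unit-header block."""
    path = Path(path)
    missing = set(schema.names) - set(df.columns)
    if missing:
        raise TableValidationError(f"dataframe missing columns {sorted(missing)}")
    with path.open("w") as fh:
        fh.write(MAGIC + "\n")
        for col, unit in schema.units.items():
            fh.write(f"# unit: {col} = {unit}\n")
        df.loc[:, list(schema.names)].to_csv(fh, index=False)


def read_table(path: str | Path, schema: TableSchema) -> pd.DataFrame:
    """Read and validate a unit-headed CSV.

    Raises :class:`TableValidationError` listing every offending row with
    its 1-based line number (header mismatches, unit mismatches,
    unparsable values, out-of-range values, duplicate keys).  An empty
    table (header only) returns an empty frame with a warning.
    """
    path = Path(path)
    header_units: dict[str, str] = {}
    data_lines: list[str] = []
    line_nos: list[int] = []
    header_row: str | None = None
    with path.open() as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                if line.startswith("# unit:"):
                    body = line[len("# unit:"):]
                    col, _, unit = body.partition("=")
                    header_units[col.strip()] = unit.strip()
                continue
            if header_row is None:
                header_row = line
                continue
            data_lines.append(line)
            line_nos.append(i)

    errors: list[str] = []
    if header_row is None:
        raise TableValidationError(f"{path}: no header row found")
    cols = [c.strip() for c in header_row.split(",")]
    if tuple(cols) != schema.names:
        raise TableValidationError(
            f"{path}: header {cols} does not match schema "
            f"{list(schema.names)}"
        )
    for col, unit in schema.units.items():
        declared = header_units.get(col)
        if declared is not None and declared != unit:
            errors.append(
                f"column {col!r}: declared unit {declared!r} != schema unit {unit!r}"
            )
    if errors:
        raise TableValidationError(f"{path}: " + "; ".join(errors))

    if not data_lines:
        warnings.warn(f"{path}: table is empty", stacklevel=2)
        return pd.DataFrame(columns=list(schema.names))

    df = pd.read_csv(
        _io.StringIO(header_row + "\n" + "\n".join(data_lines)),
        dtype={c.name: (str if c.dtype == "str" else float) for c in schema.columns},
    )
    for spec in schema.columns:
        if spec.dtype == "str":
            continue
        vals = df[spec.name]
        bad = pd.Series(False, index=df.index)
        if spec.lo is not None:
            bad |= vals < spec.lo
        if spec.hi is not None:
            bad |= vals > spec.hi
        for j in np.flatnonzero(bad.to_numpy() & vals.notna().to_numpy()):
            errors.append(
                f"line {line_nos[j]}: {spec.name} = {vals.iloc[j]} outside "
                f"[{spec.lo}, {spec.hi}] ({spec.unit})"
            )
        if spec.dtype == "int":
            df[spec.name] = vals.astype("Int64")
    if errors:
        raise TableValidationError(f"{path}: " + "; ".join(errors))
    return df
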