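"""STAR metadata tables (RELION-style loop_ blocks).

A STAR file holds one or more named data blocks; here every block is a
``loop_`` table with ``_rlnColumnName #i`` tags.  Tables round-trip
losslessly for string, integer and float columns: floats are written
with 17 significant digits (enough to reproduce any IEEE 754 double).

Lines starting with '#' are treated as comments and ignored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["MetadataTable", "StarFormatError", "read_star", "write_star"]


class StarFormatError(ValueError):
    """Malformed STAR file (duplicate blocks, ragged rows, ...)."""


@dataclass
class MetadataTable:
    """A named table of per-row metadata values."""

    name: str
    df: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if len(set(self.df.columns)) != len(self.df.columns):
            raise StarFormatError(f"duplicate column names in block '{self.name}'")

    def __len__(self) -> int:
        return len(self.df)


def _format_value(v) -> str:
    if isinstance(v, (bool, np.bool_)):
        return "1" if v else "0"
    if isinstance(v, (int, np.integer)):
        return str(int(v))
    if isinstance(v, (float, np.floating)):
        return f"{float(v):.17g}"
    s = str(v)
    return s if s else '""'


def write_star(tables: list[MetadataTable] | MetadataTable, path: str | Path) -> None:
    """Write tables as loop_ blocks; block names must be unique."""
    if isinstance(tables, MetadataTable):
        tables = [tables]
    names = [t.name for t in tables]
    if len(set(names)) != len(names):
        raise StarFormatError(f"duplicate block names {names}")
    lines: list[str] = ["# written by cryoclass", ""]
    for t in tables:
        lines.append(f"data_{t.name}")
        lines.append("")
        lines.append("loop_")
        for i, col in enumerate(t.df.columns, start=1):
            lines.append(f"_{col} #{i}")
        for _, row in t.df.iterrows():
            lines.append(" ".join(_format_value(v) for v in row))
        lines.append("")
    Path(path).write_text("\n".join(lines) + "\n")


def _convert_column(values: list[str]) -> pd.Series:
    for caster in (np.int64, np.float64):
        try:
            return pd.Series([caster(v) for v in values])
        except (ValueError, OverflowError):
            continue
    return pd.Series(values, dtype=object)


def read_star(path: str | Path) -> list[MetadataTable]:
    """Parse a STAR file into a list of :class:`MetadataTable`.

    Raises :class:`StarFormatError` on duplicate block names or rows whose
    field count does not match the declared column tags.
    """
    lines = Path(path).read_text().splitlines()
    tables: list[MetadataTable] = []
    seen: set[str] = set()
    i = 0
    n = len(lines)
    while i < n:
        line = lines[i].strip()
        if not line or line.startswith("#"):
            i += 1
            continue
        if not line.startswith("data_"):
            raise StarFormatError(f"unexpected content outside a data block: '{line}'")
        name = line[len("data_"):]
        if name in seen:
            raise StarFormatError(f"duplicate block name '{name}'")
        seen.add(name)
        i += 1
        # find loop_
        while i < n and (not lines[i].strip() or lines[i].strip().startswith("#")):
            i += 1
        if i >= n or lines[i].strip() != "loop_":
            raise StarFormatError(f"block '{name}' has no loop_ section")
        i += 1
        columns: list[str] = []
        while i < n:
            s = lines[i].strip()
            if s.startswith("_"):
                columns.append(s.split()[0][1:])
                i += 1
            elif not s or s.startswith("#"):
                i += 1
                if columns:
                    break
            else:
                break
        rows: list[list[str]] = []
        while i < n:
            s = lines[i].strip()
            if not s or s.startswith("#") or s.startswith("data_"):
                break
            fields = s.split()
            if len(fields) != len(columns):
                raise StarFormatError(
                    f"ragged row in block '{name}': expected {len(columns)} "
                    f"fields, got {len(fields)}")
            rows.append(fields)
            i += 1
        if rows:
            raw = {c: [r[j] for r in rows] for j, c in enumerate(columns)}
            df = pd.DataFrame({c: _convert_column(v) for c, v in raw.items()})
        else:
            df = pd.DataFrame({c: pd.Series(dtype=object) for c in columns})
        tables.append(MetadataTable(name=name, df=df))
    return tables
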