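"""Plain-text table formats.

All tables are tab-delimited text with a mandatory header row.

Uptake table: first two columns ``animal_id`` and ``group``, then one column
per region.  Exactly two group levels are required; blank cells load as
missing values.  Section-level and exploration-record tables follow the
column lists documented in :mod:`dgconnect.lcgu` and
:mod:`dgconnect.behavior`.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import TableFormatError

__all__ = [
    "load_uptake_table",
    "write_uptake_table",
    "load_sections",
    "load_standards",
    "load_exploration",
    "write_table",
]

SEP = "\t"


def _read(path, **kwargs) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep=SEP, **kwargs)
    except Exception as exc:  # noqa: BLE001 - re-raise with file context
        raise TableFormatError(f"cannot parse {path}: {exc}") from exc


def load_uptake_table(path) -> pd.DataFrame:
    """Load and validate an animal x region uptake-ratio table."""
    df = _read(path, dtype={0: str, 1: str})
    if list(df.columns[:2]) != ["animal_id", "group"]:
        raise TableFormatError(
            f"{path}: first two columns must be 'animal_id' and 'group', "
            f"got {list(df.columns[:2])}"
        )
    if df.shape[1] < 3:
        raise TableFormatError(f"{path}: no region columns found")
    dup = df["animal_id"][df["animal_id"].duplicated()]
    if not dup.empty:
        raise TableFormatError(f"{path}: duplicate animal_id value(s): {sorted(set(dup))}")
    levels = list(dict.fromkeys(df["group"].dropna()))
    if len(levels) != 2:
        raise TableFormatError(
            f"{path}: expected exactly two group levels, found {levels}"
        )
    regions = df.columns[2:]
    for col in regions:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df[col].notna() & coerced.isna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise TableFormatError(
                f"{path}: non-numeric value {df[col].iloc[row]!r} in column {col!r}, "
                f"row {row + 2} (animal {df['animal_id'].iloc[row]!r})"
            )
        df[col] = coerced
    return df


def write_uptake_table(table: pd.DataFrame, path) -> None:
    write_table(table, path)


def write_table(table: pd.DataFrame, path) -> None:
    """Write any result table as tab-delimited text (deterministic float repr)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    buf = _io.StringIO()
    table.to_csv(buf, sep=SEP, index=False, lineterminator="\n", float_format="%.10g")
    Path(path).write_text(buf.getvalue())


def load_sections(path) -> pd.DataFrame:
    """Load a section-level measurement table."""
    df = _read(path)
    required = {"animal_id", "region", "section_index", "value"}
    missing = required - set(df.columns)
    if missing:
        raise TableFormatError(f"{path}: missing column(s) {sorted(missing)}")
    return df


def load_standards(path) -> pd.DataFrame:
    """Load a calibration-standards table (activity, optical_density)."""
    df = _read(path)
    missing = {"activity", "optical_density"} - set(df.columns)
    if missing:
        raise TableFormatError(f"{path}: missing column(s) {sorted(missing)}")
    return df


def load_exploration(path) -> pd.DataFrame:
    """Load behavioural exploration records."""
    df = _read(path)
    missing = {"animal_id", "group", "phase", "time_A", "time_B"} - set(df.columns)
    if missing:
        raise TableFormatError(f"{path}: missing column(s) {sorted(missing)}")
    return df
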