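"""Reading and writing the study's tabular formats.

Transect tables: one row per leg —
``timestamp  leg_id  usable_minutes  <taxon> ...`` (TSV/CSV).
Hourly environment tables: ``timestamp  ns_velocity  ew_velocity
temperature  oxygen  chlorophyll  density`` (extra variables allowed).
Timestamps are ISO-8601 naive local time.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .synthetic import TransectRecord

__all__ = [
    "read_transects",
    "read_env_table",
    "transect_records",
    "TRANSECT_META_COLUMNS",
    "ENV_REQUIRED_COLUMNS",
]

TRANSECT_META_COLUMNS = ["timestamp", "leg_id", "usable_minutes"]
ENV_REQUIRED_COLUMNS = [
    "timestamp",
    "ns_velocity",
    "ew_velocity",
    "temperature",
    "oxygen",
    "chlorophyll",
    "density",
]


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    return pd.read_csv(path, sep=sep)


def read_transects(path: str | Path) -> pd.DataFrame:
    """Read a transect-leg table; taxa are every non-metadata column."""
    df = _read_table(path)
    missing = [c for c in TRANSECT_META_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing transect columns {missing}")
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    return df


def read_env_table(path: str | Path, required: bool = True) -> pd.DataFrame:
    """Read an hourly environmental table."""
    df = _read_table(path)
    if "timestamp" not in df.columns:
        raise ValueError(f"{path}: missing 'timestamp' column")
    if required:
        missing = [c for c in ENV_REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing environment columns {missing}")
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    return df


def transect_records(df: pd.DataFrame) -> list[TransectRecord]:
    """Turn a transect table into per-leg records."""
    taxa = [c for c in df.columns if c not in TRANSECT_META_COLUMNS]
    records = []
    for _, row in df.iterrows():
        records.append(
            TransectRecord(
                timestamp=pd.Timestamp(row["timestamp"]),
                leg_id=str(row["leg_id"]),
                usable_minutes=float(row["usable_minutes"]),
                counts={t: int(row[t]) for t in taxa},
            )
        )
    return records
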