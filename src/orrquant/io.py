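"""Table readers/writers with schema validation.

All tables are plain CSV.  Readers validate mandatory columns and report
the missing ones by name; unknown columns are preserved on round trip.
Coordinates in region tables are micron, 0-based, half-open region
intervals [x_start, x_start + length).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

REGION_COLUMNS = (
    "eye_id", "condition", "region_id", "x_start_um", "mean_orr", "sd_orr",
    "electrode_id", "in_pocket", "measurable",
)

SPIKE_COLUMNS = (
    "stim_electrode", "channel", "hemisphere", "x_mm", "y_mm",
    "current_uA", "spikes",
)


class SchemaError(ValueError):
    """A table does not conform to its expected schema."""


def _read_checked(path, required: tuple[str, ...]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input table not found: {path}")
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise SchemaError(f"malformed CSV {path}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory columns {missing}")
    return df


def read_region_table(path) -> pd.DataFrame:
    """Read a per-region ORr table (see :data:`REGION_COLUMNS`)."""
    return _read_checked(path, REGION_COLUMNS)


def write_region_table(df: pd.DataFrame, path) -> None:
    missing = [c for c in REGION_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"region table missing columns {missing}")
    df.to_csv(path, index=False)


def read_spike_table(path) -> pd.DataFrame:
    """Read a long-format cortical spike table (see :data:`SPIKE_COLUMNS`)."""
    return _read_checked(path, SPIKE_COLUMNS)


def write_spike_table(df: pd.DataFrame, path) -> None:
    missing = [c for c in SPIKE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"spike table missing columns {missing}")
    df.to_csv(path, index=False)


def write_metric_table(df: pd.DataFrame, path) -> None:
    """Write any tidy metric table as CSV."""
    df.to_csv(path, index=False)


def read_metric_table(path) -> pd.DataFrame:
    return _read_checked(path, ())
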