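"""Event-table reading, validation and writing.

The on-disk format is a plain UTF-8 CSV with a header and one row per fly:
``fly_id, lab, cohort, genotype, sex, diet, vial, time_days, event`` with
nonnegative real times in days and a strictly binary event indicator
(1 = observed death, 0 = right-censored).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field  # noqa: F401
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import EVENT_COLUMNS

__all__ = ["EventTable", "EventTableError", "read_event_table", "write_event_table"]

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = tuple(EVENT_COLUMNS)


class EventTableError(ValueError):
    """Malformed event table; message carries offending line numbers."""


@dataclass
class EventTable:
    """Validated tabular container of per-fly survival records."""

    data: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.data)

    def design_levels(self) -> dict:
        return {
            col: sorted(self.data[col].astype(str).unique())
            for col in ("lab", "cohort", "genotype", "sex", "diet")
        }


def _validate(df: pd.DataFrame, path, strict: bool) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise EventTableError(f"{path}: missing required column(s) {missing}")
    extra = [c for c in df.columns if c not in REQUIRED_COLUMNS]
    if extra:
        if strict:
            raise EventTableError(f"{path}: unknown column(s) {extra} (strict mode)")
        logger.warning("%s: ignoring unknown column(s) %s", path, extra)
        df = df[list(REQUIRED_COLUMNS)]

    # line numbers are 1-based including the header row
    lines = df.index.to_numpy() + 2

    times = pd.to_numeric(df["time_days"], errors="coerce")
    bad = times.isna().to_numpy() | ~np.isfinite(times.to_numpy(dtype=float))
    if bad.any():
        raise EventTableError(
            f"{path}: non-numeric or non-finite time_days on line(s) "
            f"{lines[bad][:10].tolist()}"
        )
    neg = (times.to_numpy(dtype=float) < 0)
    if neg.any():
        raise EventTableError(
            f"{path}: negative time_days on line(s) {lines[neg][:10].tolist()}"
        )

    events = pd.to_numeric(df["event"], errors="coerce")
    bad_ev = events.isna().to_numpy() | ~np.isin(events.to_numpy(), (0, 1))
    if bad_ev.any():
        raise EventTableError(
            f"{path}: event must be 0 or 1; offending line(s) "
            f"{lines[bad_ev][:10].tolist()}"
        )

    out = df.copy()
    out["time_days"] = times.astype(float)
    out["event"] = events.astype(np.int64)
    for col in ("fly_id", "lab", "cohort", "genotype", "sex", "diet", "vial"):
        out[col] = out[col].astype(str)
    return out


def read_event_table(path, strict: bool = False, metadata: dict | None = None) -> EventTable:
    """Read and validate an event-table CSV.

    ``strict=True`` rejects unknown columns; the default warns and drops
    them. Malformed rows are reported with their 1-based file line numbers.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype={"cohort": str, "lab": str}, keep_default_na=False)
    if df.empty:
        raise EventTableError(f"{path}: no data rows")
    return EventTable(data=_validate(df, path, strict), metadata=dict(metadata or {}))


def write_event_table(table: EventTable | pd.DataFrame, path) -> Path:
    """Write an event table as CSV; returns the path written."""
    df = table.data if isinstance(table, EventTable) else table
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise EventTableError(f"cannot write table: missing column(s) {missing}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df[list(REQUIRED_COLUMNS)].to_csv(path, index=False)
    return path
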