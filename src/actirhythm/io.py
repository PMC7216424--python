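"""Readers and writers for activity series, event logs and cohort tables.

All tabular formats are plain CSV with ISO-8601 timestamps and a header row:

* activity:  ``timestamp,activity``
* events:    ``type,start,end`` (empty ``end`` marks a point event); a JSON
  list of ``{"type":..., "start":..., "end":...}`` objects is also accepted
* cohort:    ``patient_id,age,sex,etiology,months_since_injury,diagnosis,
  crs_r_sum,excluded``
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .types import (
    ActivitySeries,
    CohortTable,
    EventLog,
    EventRecord,
    EventType,
    ParseError,
    PatientRecord,
    ValidationError,
)

__all__ = [
    "read_activity_csv",
    "write_activity_csv",
    "read_event_log",
    "write_event_log",
    "read_cohort_csv",
    "write_cohort_csv",
    "load_table1_fixture",
]

PathLike = Union[str, Path]


def read_activity_csv(path: PathLike, patient_id: str | None = None) -> ActivitySeries:
    """Read a per-epoch activity series from a ``timestamp,activity`` CSV.

    Timestamps must be strictly increasing and equally spaced; the epoch
    length is inferred from the spacing.
    """
    path = Path(path)
    df = pd.read_csv(path)
    for col in ("timestamp", "activity"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    if len(df) < 2:
        raise ParseError(f"{path}: need at least two epochs to infer spacing")
    try:
        ts = pd.to_datetime(df["timestamp"], format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise ParseError(f"{path}: unparseable timestamp ({exc})") from exc
    deltas = ts.diff().dt.total_seconds().to_numpy()[1:]
    if np.any(deltas <= 0):
        row = int(np.argmax(deltas <= 0)) + 1
        raise ParseError(
            f"{path}: timestamps not strictly increasing at row {row + 1} "
            f"(data row {row}, value {df['timestamp'].iloc[row]})"
        )
    step = deltas[0]
    if np.any(deltas != step):
        row = int(np.argmax(deltas != step)) + 1
        raise ParseError(
            f"{path}: irregular spacing at row {row + 1}: expected {step:.0f} s, "
            f"got {deltas[row - 1]:.0f} s"
        )
    if step != int(step):
        raise ParseError(f"{path}: epoch spacing must be a whole number of seconds")
    values = pd.to_numeric(df["activity"], errors="coerce").to_numpy(dtype=float)
    if np.any(~np.isfinite(values)):
        row = int(np.argmax(~np.isfinite(values)))
        raise ParseError(f"{path}: non-numeric activity at data row {row}")
    if np.any(values < 0):
        row = int(np.argmax(values < 0))
        raise ValidationError(f"{path}: negative activity at data row {row}")
    return ActivitySeries(
        patient_id=patient_id or path.stem,
        start_time=ts.iloc[0].to_pydatetime(),
        epoch_seconds=int(step),
        values=values,
    )


def write_activity_csv(series: ActivitySeries, path: PathLike) -> None:
    df = pd.DataFrame(
        {
            "timestamp": [t.isoformat() for t in series.timestamps()],
            "activity": series.values,
        }
    )
    df.to_csv(path, index=False)


def _parse_event_row(etype: str, start: str, end: str | None) -> EventRecord:
    try:
        event_type = EventType(etype)
    except ValueError:
        allowed = ", ".join(t.value for t in EventType)
        raise ParseError(f"unknown event type {etype!r}; allowed: {allowed}") from None
    start_ts = pd.Timestamp(start).to_pydatetime()
    end_ts = None
    if end is not None and str(end).strip() != "" and not pd.isna(end):
        end_ts = pd.Timestamp(end).to_pydatetime()
    return EventRecord(event_type=event_type, start=start_ts, end=end_ts)


def read_event_log(path: PathLike, patient_id: str | None = None) -> EventLog:
    """Read a typed event log from CSV (``type,start,end``) or a JSON list."""
    path = Path(path)
    events: list[EventRecord] = []
    if path.suffix.lower() == ".json":
        rows = json.loads(path.read_text())
        for row in rows:
            events.append(_parse_event_row(row["type"], row["start"], row.get("end")))
    else:
        df = pd.read_csv(path, dtype=str)
        for col in ("type", "start"):
            if col not in df.columns:
                raise ParseError(f"{path}: missing required column {col!r}")
        if "end" not in df.columns:
            df["end"] = None
        for _, row in df.iterrows():
            events.append(_parse_event_row(row["type"], row["start"], row["end"]))
    return EventLog(patient_id=patient_id or path.stem, events=events).sorted()


def write_event_log(log: EventLog, path: PathLike) -> None:
    path = Path(path)
    rows = [
        {
            "type": e.event_type.value,
            "start": e.start.isoformat(),
            "end": e.end.isoformat() if e.end is not None else "",
        }
        for e in log.events
    ]
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(rows, indent=1))
    else:
        pd.DataFrame(rows, columns=["type", "start", "end"]).to_csv(path, index=False)


_COHORT_COLUMNS = [
    "patient_id",
    "age",
    "sex",
    "etiology",
    "months_since_injury",
    "diagnosis",
    "crs_r_sum",
    "excluded",
]


def read_cohort_csv(path: PathLike) -> CohortTable:
    df = pd.read_csv(path)
    missing = [c for c in _COHORT_COLUMNS[:-1] if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing cohort columns {missing}")
    records = []
    for _, row in df.iterrows():
        records.append(
            PatientRecord(
                patient_id=str(row["patient_id"]),
                age=float(row["age"]),
                sex=str(row["sex"]),
                etiology=str(row["etiology"]),
                months_since_injury=float(row["months_since_injury"]),
                diagnosis=str(row["diagnosis"]),
                crs_r_sum=int(row["crs_r_sum"]),
                excluded=bool(row["excluded"]) if "excluded" in df.columns else False,
            )
        )
    return CohortTable(records)


def write_cohort_csv(cohort: CohortTable, path: PathLike) -> None:
    rows = [
        {
            "patient_id": r.patient_id,
            "age": r.age,
            "sex": r.sex,
            "etiology": r.etiology,
            "months_since_injury": r.months_since_injury,
            "diagnosis": r.diagnosis,
            "crs_r_sum": r.crs_r_sum,
            "excluded": r.excluded,
        }
        for r in cohort.records
    ]
    pd.DataFrame(rows, columns=_COHORT_COLUMNS).to_csv(path, index=False)


def load_table1_fixture() -> CohortTable:
    """The packaged 30-patient demographic table of the reference cohort.

    One patient (P26) is flagged ``excluded``: after cleaning, hardly any
    activity remained, so the analyses run on the other 29 patients.
    """
    with resources.as_file(
        resources.files("actirhythm.data").joinpath("table1.csv")
    ) as p:
        return read_cohort_csv(p)
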