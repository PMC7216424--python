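"""Core domain types for actigraphy series, ward event logs and cohort metadata.

The central object is :class:`ActivitySeries`: a regularly sampled sequence of
nonnegative activity counts (arbitrary units) with a start time and an epoch
length. Event logs carry the typed start/stop intervals and single-press point
events recorded at the bedside (visits, nursing, therapy, wheelchair
mobilisations, device-off spans, medication, lights on/off, ...), which drive
the passive-movement correction. Cohort metadata mirrors a clinical table of
disorders-of-consciousness patients (diagnosis UWS / MCS / EMCS, etiology
TBI / NTBI, CRS-R behavioural scores).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterator, Mapping, Optional

import numpy as np

__all__ = [
    "EventType",
    "POINT_EVENT_TYPES",
    "REMOVABLE_EVENT_TYPES",
    "ActivitySeries",
    "EventRecord",
    "EventLog",
    "PatientRecord",
    "CohortTable",
    "ActirhythmError",
    "ParseError",
    "ValidationError",
    "UncorrectableSeriesError",
]


class ActirhythmError(Exception):
    """Base class for errors raised by this package."""


class ParseError(ActirhythmError, ValueError):
    """A file could not be parsed into a domain object."""


class ValidationError(ActirhythmError, ValueError):
    """A domain invariant was violated."""


class UncorrectableSeriesError(ActirhythmError):
    """Raised when removal leaves too little data to impute or analyse.

    Mirrors the clinical situation of a recording with hardly any activity
    left once passive movements are cleaned out: such a patient cannot be
    analysed and must be excluded.
    """


class EventType(str, Enum):
    """Typed bedside events.

    Interval events have a start and an end button; point events are single
    presses and carry no duration.
    """

    VISIT = "visit"
    NURSING = "nursing"
    THERAPY = "therapy"
    WHEELCHAIR = "wheelchair"
    MOBILIZATION_OUTSIDE = "mobilization_outside"
    DEVICE_OFF = "device_off"
    CRS_R = "crs_r"
    MEDICATION = "medication"
    NUTRITION = "nutrition"
    LIGHTS_ON = "lights_on"
    LIGHTS_OFF = "lights_off"
    EYES_OPEN = "eyes_open"
    EYES_CLOSED = "eyes_closed"


#: Single-press events: no duration, never produce removal intervals.
POINT_EVENT_TYPES = frozenset(
    {
        EventType.MEDICATION,
        EventType.NUTRITION,
        EventType.LIGHTS_ON,
        EventType.LIGHTS_OFF,
        EventType.EYES_OPEN,
        EventType.EYES_CLOSED,
    }
)

#: Interval events whose spans are removed from the activity series.
REMOVABLE_EVENT_TYPES = frozenset(
    {
        EventType.VISIT,
        EventType.NURSING,
        EventType.THERAPY,
        EventType.WHEELCHAIR,
        EventType.MOBILIZATION_OUTSIDE,
        EventType.DEVICE_OFF,
        EventType.CRS_R,
    }
)


@dataclass
class ActivitySeries:
    """Regularly sampled per-epoch activity counts.

    Parameters
    ----------
    patient_id
        Identifier of the recording.
    start_time
        Timezone-naive local clock time of the first epoch. Each epoch is
        labelled by its start and covers ``[t, t + epoch_seconds)``.
    epoch_seconds
        Epoch length in seconds; must divide 3600 (60 after downsampling).
    values
        Nonnegative, finite activity values in arbitrary units.
    """

    patient_id: str
    start_time: dt.datetime
    epoch_seconds: int
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValidationError("values must be one-dimensional")
        if self.epoch_seconds <= 0 or 3600 % self.epoch_seconds != 0:
            raise ValidationError(
                f"epoch_seconds must be a positive divisor of 3600, got {self.epoch_seconds}"
            )
        if self.start_time.tzinfo is not None:
            raise ValidationError("start_time must be timezone-naive local clock time")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("activity values must be finite")
        if self.values.size and self.values.min() < 0:
            i = int(np.argmax(self.values < 0))
            raise ValidationError(f"negative activity value {self.values[i]} at epoch {i}")

    @property
    def n_epochs(self) -> int:
        return int(self.values.size)

    @property
    def end_time(self) -> dt.datetime:
        """End of the last epoch (exclusive)."""
        return self.start_time + dt.timedelta(seconds=self.n_epochs * self.epoch_seconds)

    @property
    def span_hours(self) -> float:
        """Distance between the first and last epoch *labels* in hours."""
        return (self.n_epochs - 1) * self.epoch_seconds / 3600.0

    def timestamps(self) -> list[dt.datetime]:
        step = dt.timedelta(seconds=self.epoch_seconds)
        return [self.start_time + i * step for i in range(self.n_epochs)]

    def epoch_hours(self) -> np.ndarray:
        """Epoch labels as hours since ``start_time`` (the metric time axis)."""
        return np.arange(self.n_epochs) * (self.epoch_seconds / 3600.0)

    def seconds_of_day(self) -> np.ndarray:
        """Local clock time of each epoch start, as seconds since midnight."""
        first = (
            self.start_time.hour * 3600
            + self.start_time.minute * 60
            + self.start_time.second
        )
        return (first + np.arange(self.n_epochs, dtype=np.int64) * self.epoch_seconds) % 86400

    def with_values(self, values: np.ndarray) -> "ActivitySeries":
        return ActivitySeries(self.patient_id, self.start_time, self.epoch_seconds, values)

    def epoch_index(self, when: dt.datetime) -> float:
        """Fractional epoch index of a timestamp relative to the grid."""
        return (when - self.start_time).total_seconds() / self.epoch_seconds


@dataclass(frozen=True)
class EventRecord:
    """One typed bedside event: an interval (start/end) or a point press."""

    event_type: EventType
    start: dt.datetime
    end: Optional[dt.datetime] = None

    def __post_init__(self) -> None:
        if self.event_type in POINT_EVENT_TYPES:
            if self.end is not None:
                raise ValidationError(
                    f"{self.event_type.value} is a point event and cannot have an end"
                )
        else:
            if self.end is None:
                raise ValidationError(
                    f"{self.event_type.value} is an interval event and requires an end"
                )
            if self.end <= self.start:
                raise ValidationError(
                    f"event end {self.end} must be after start {self.start}"
                )

    @property
    def is_point(self) -> bool:
        return self.end is None


@dataclass
class EventLog:
    """All bedside events recorded for one patient."""

    patient_id: str
    events: list[EventRecord] = field(default_factory=list)

    def sorted(self) -> "EventLog":
        return EventLog(self.patient_id, sorted(self.events, key=lambda e: e.start))

    def __iter__(self) -> Iterator[EventRecord]:
        return iter(self.events)

    def __len__(self) -> int:
        return len(self.events)


_DIAGNOSES = ("UWS", "MCS", "EMCS")
_ETIOLOGIES = ("TBI", "NTBI")
_SEXES = ("M", "F")


@dataclass(frozen=True)
class PatientRecord:
    """Clinical metadata for one patient.

    ``diagnosis`` follows the behavioural classification of disorders of
    consciousness: UWS (unresponsive wakefulness syndrome), MCS (minimally
    conscious state) or EMCS (exit MCS). ``crs_r_sum`` is the Coma Recovery
    Scale - Revised sum score (0-23); subscale scores are optional.
    """

    patient_id: str
    age: float
    sex: str
    etiology: str
    months_since_injury: float
    diagnosis: str
    crs_r_sum: int
    crs_r_subscales: Optional[Mapping[str, int]] = None
    excluded: bool = False

    def __post_init__(self) -> None:
        if self.diagnosis not in _DIAGNOSES:
            raise ValidationError(f"diagnosis must be one of {_DIAGNOSES}, got {self.diagnosis!r}")
        if self.etiology not in _ETIOLOGIES:
            raise ValidationError(f"etiology must be one of {_ETIOLOGIES}, got {self.etiology!r}")
        if self.sex not in _SEXES:
            raise ValidationError(f"sex must be one of {_SEXES}, got {self.sex!r}")
        if not 0 <= self.crs_r_sum <= 23:
            raise ValidationError(f"crs_r_sum must be in 0..23, got {self.crs_r_sum}")
        if self.months_since_injury < 0:
            raise ValidationError("months_since_injury must be nonnegative")

    @property
    def diagnosis_group(self) -> str:
        """Pooled two-level grouping: UWS vs MCS_EMCS (MCS and EMCS combined)."""
        return "UWS" if self.diagnosis == "UWS" else "MCS_EMCS"


@dataclass
class CohortTable:
    """A cohort of patients with unique identifiers."""

    records: list[PatientRecord]

    def __post_init__(self) -> None:
        ids = [r.patient_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValidationError("patient_id values must be unique")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[PatientRecord]:
        return iter(self.records)

    def get(self, patient_id: str) -> PatientRecord:
        for r in self.records:
            if r.patient_id == patient_id:
                return r
        raise KeyError(patient_id)

    def analyzed(self) -> "CohortTable":
        """The cohort without patients flagged as excluded."""
        return CohortTable([r for r in self.records if not r.excluded])

    def group_ids(self, group: str) -> list[str]:
        """Patient ids in a pooled diagnosis group (``UWS`` or ``MCS_EMCS``)."""
        return [r.patient_id for r in self.records if r.diagnosis_group == group]
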