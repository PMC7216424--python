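"""Passive-movement correction of actigraphy series.

Care-dependent, largely immobile patients do not generate all the movement a
wrist actigraph records: nursing, therapy, visitors and wheelchair transfers
move the instrumented limb passively. This module removes the spans of the
recording during which such bedside events were logged, pads them (staff tend
to press "start" late), merges overlapping spans, and fills the gaps with a
two-sided median imputation so that downstream rhythm metrics, which need a
gap-free series, can be computed.

Removal + imputation rule
-------------------------
Each removable logged interval is widened by an event-type-specific pad
(defaults: 5 min either side of nursing, 10 min either side of visits and
wheelchair use), snapped outward to the epoch grid, and merged with any
overlapping or touching interval. Within each merged gap the first half of
the removed epochs is replaced by the median activity of the 10 min of clean
data immediately preceding the gap and the second half by the median of the
10 min immediately following it; if one side has no clean context the other
side's median fills the whole gap.
"""

from __future__ import annotations

import datetime as dt
import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .types import (
    ActivitySeries,
    EventLog,
    EventType,
    REMOVABLE_EVENT_TYPES,
    UncorrectableSeriesError,
    ValidationError,
)

__all__ = [
    "PaddingPolicy",
    "RemovalInterval",
    "CorrectedSeries",
    "downsample_to_minutes",
    "build_removal_intervals",
    "impute_interval",
    "correct_series",
    "removed_fraction_report",
]

logger = logging.getLogger(__name__)

_DEFAULT_PADS: dict[EventType, tuple[float, float]] = {
    EventType.NURSING: (5.0, 5.0),
    EventType.VISIT: (10.0, 10.0),
    EventType.WHEELCHAIR: (10.0, 10.0),
    EventType.THERAPY: (0.0, 0.0),
    EventType.MOBILIZATION_OUTSIDE: (0.0, 0.0),
    EventType.DEVICE_OFF: (0.0, 0.0),
    EventType.CRS_R: (0.0, 0.0),
}


@dataclass(frozen=True)
class PaddingPolicy:
    """Per-event-type removal pads in minutes, applied before and after.

    The defaults encode the correction rule for unreliable log timing:
    nursing activities are padded by 5 min on each side, visits and
    wheelchair use by 10 min; the remaining removable types are removed
    exactly as logged.
    """

    pads: Mapping[EventType, tuple[float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_PADS)
    )

    def __post_init__(self) -> None:
        for etype, (before, after) in self.pads.items():
            if before < 0 or after < 0:
                raise ValidationError(f"pads must be nonnegative ({etype.value})")

    def pad_minutes(self, event_type: EventType) -> tuple[float, float]:
        return tuple(self.pads.get(event_type, (0.0, 0.0)))

    def replace(self, **overrides: tuple[float, float]) -> "PaddingPolicy":
        """A copy with pads overridden by event-type name, e.g. ``nursing=(3, 3)``."""
        pads = dict(self.pads)
        for name, pad in overrides.items():
            pads[EventType(name)] = (float(pad[0]), float(pad[1]))
        return PaddingPolicy(pads)


@dataclass(frozen=True)
class RemovalInterval:
    """A maximal removed span, snapped outward to epoch boundaries."""

    start: dt.datetime
    end: dt.datetime
    source_types: frozenset[EventType]

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValidationError("removal interval end must be after start")

    def epoch_slice(self, series: ActivitySeries) -> slice:
        i0 = int(round(series.epoch_index(self.start)))
        i1 = int(round(series.epoch_index(self.end)))
        return slice(max(i0, 0), min(i1, series.n_epochs))


@dataclass
class CorrectedSeries:
    """An activity series with passive-movement spans imputed in place.

    ``removed`` is a boolean per-epoch mask (True = removed and imputed);
    ``imputed_from`` records, per epoch, which side's median filled it
    (``"before"``, ``"after"`` or ``"none"`` for observed epochs).
    """

    series: ActivitySeries
    removed: np.ndarray
    intervals: list[RemovalInterval]
    imputed_from: np.ndarray

    @property
    def removed_fraction(self) -> float:
        return float(self.removed.mean()) if self.removed.size else 0.0

    @property
    def mask(self) -> np.ndarray:
        """Per-epoch labels ``observed`` / ``removed_imputed``."""
        return np.where(self.removed, "removed_imputed", "observed")


def downsample_to_minutes(raw: ActivitySeries, aggregator: str = "sum") -> ActivitySeries:
    """Aggregate a sub-minute series to one value per minute.

    The per-minute value is the sum (default; count-like semantics) or mean
    of the raw values in that minute; a trailing partial minute is dropped.
    """
    if raw.n_epochs == 0:
        raise ValidationError("cannot downsample an empty series")
    if raw.epoch_seconds >= 60:
        raise ValidationError("input is already at minute resolution or coarser")
    if 60 % raw.epoch_seconds != 0:
        raise ValidationError(
            f"epoch of {raw.epoch_seconds} s does not evenly divide one minute"
        )
    per_min = 60 // raw.epoch_seconds
    n_minutes = raw.n_epochs // per_min
    if n_minutes == 0:
        raise ValidationError("series shorter than one full minute")
    block = raw.values[: n_minutes * per_min].reshape(n_minutes, per_min)
    if aggregator == "sum":
        values = block.sum(axis=1)
    elif aggregator == "mean":
        values = block.mean(axis=1)
    else:
        raise ValidationError(f"unknown aggregator {aggregator!r}")
    return ActivitySeries(raw.patient_id, raw.start_time, 60, values)


def _snap_to_grid(
    series: ActivitySeries, start: dt.datetime, end: dt.datetime
) -> tuple[int, int]:
    """Outward snap: floor the start and ceil the end to epoch boundaries."""
    i0 = math.floor(series.epoch_index(start))
    i1 = math.ceil(series.epoch_index(end))
    return max(i0, 0), min(i1, series.n_epochs)


def build_removal_intervals(
    log: EventLog,
    policy: PaddingPolicy | None = None,
    series: ActivitySeries | None = None,
    extra_intervals: Optional[Sequence[tuple[dt.datetime, dt.datetime]]] = None,
) -> list[RemovalInterval]:
    """Padded, merged removal intervals for all removable logged events.

    Interval events of removable type (visits, nursing, therapy, wheelchair,
    outside mobilisations, device-off spans, behavioural assessments) are
    widened by the policy pads, clipped to the series span, snapped outward
    to epoch boundaries and merged into maximal disjoint intervals. Point
    events never produce removal. ``extra_intervals`` accepts additional
    (start, end) spans, the hook for manual screening of residual artifacts.
    """
    if series is None:
        raise ValidationError("series is required to snap intervals to its epoch grid")
    policy = policy or PaddingPolicy()
    raw: list[tuple[int, int, set[EventType]]] = []
    for event in log:
        if event.is_point or event.event_type not in REMOVABLE_EVENT_TYPES:
            continue
        before, after = policy.pad_minutes(event.event_type)
        start = event.start - dt.timedelta(minutes=before)
        end = event.end + dt.timedelta(minutes=after)
        if end <= series.start_time or start >= series.end_time:
            logger.info(
                "event %s %s-%s outside recording span; ignored",
                event.event_type.value,
                event.start,
                event.end,
            )
            continue
        i0, i1 = _snap_to_grid(series, start, end)
        if i1 > i0:
            raw.append((i0, i1, {event.event_type}))
    for span in extra_intervals or []:
        start, end = span
        if end <= series.start_time or start >= series.end_time:
            continue
        i0, i1 = _snap_to_grid(series, start, end)
        if i1 > i0:
            raw.append((i0, i1, set()))

    if not raw:
        return []
    raw.sort(key=lambda r: (r[0], r[1]))
    merged: list[tuple[int, int, set[EventType]]] = [
        (raw[0][0], raw[0][1], set(raw[0][2]))
    ]
    for i0, i1, types in raw[1:]:
        m0, m1, mtypes = merged[-1]
        if i0 <= m1:  # overlap or touching: one contiguous removed span
            merged[-1] = (m0, max(m1, i1), mtypes | types)
        else:
            merged.append((i0, i1, set(types)))
    step = dt.timedelta(seconds=series.epoch_seconds)
    return [
        RemovalInterval(
            start=series.start_time + i0 * step,
            end=series.start_time + i1 * step,
            source_types=frozenset(types),
        )
        for i0, i1, types in merged
    ]


def _side_median(
    values: np.ndarray,
    removed: np.ndarray,
    start: int,
    direction: int,
    n_context: int,
) -> float | None:
    """Median of up to ``n_context`` clean epochs walking from ``start``.

    Epochs inside any removal interval are skipped, not counted: the context
    must be uncontaminated, so it extends past neighbouring removed spans.
    """
    picked: list[float] = []
    i = start
    while 0 <= i < values.size and len(picked) < n_context:
        if not removed[i]:
            picked.append(values[i])
        i += direction
    if not picked:
        return None
    return float(np.median(picked))


def impute_interval(
    series: ActivitySeries,
    interval: RemovalInterval,
    context_minutes: int = 10,
    removed_mask: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided median imputation for one removal interval.

    Returns ``(values, provenance)`` for the epochs of the interval: the
    first ``ceil(n/2)`` epochs take the median of up to ``context_minutes``
    of clean data before the interval, the rest the median of the clean data
    after it. A side without any clean context falls back to the other side;
    if neither side has context the series is uncorrectable.
    """
    if context_minutes <= 0:
        raise ValidationError("context_minutes must be positive")
    sl = interval.epoch_slice(series)
    n = sl.stop - sl.start
    if n <= 0:
        raise ValidationError("interval does not overlap the series")
    if removed_mask is None:
        removed_mask = np.zeros(series.n_epochs, dtype=bool)
        removed_mask[sl] = True
    n_context = int(context_minutes * 60 // series.epoch_seconds)
    before = _side_median(series.values, removed_mask, sl.start - 1, -1, n_context)
    after = _side_median(series.values, removed_mask, sl.stop, +1, n_context)
    if before is None and after is None:
        raise UncorrectableSeriesError(
            f"uncorrectable series {series.patient_id!r}: no clean context on "
            "either side of a removal interval"
        )
    n_first = -(-n // 2)  # ceil: the preceding median gets the extra epoch
    values = np.empty(n)
    provenance = np.empty(n, dtype=object)
    first_val, first_src = (before, "before") if before is not None else (after, "after")
    second_val, second_src = (after, "after") if after is not None else (before, "before")
    values[:n_first] = first_val
    provenance[:n_first] = first_src
    values[n_first:] = second_val
    provenance[n_first:] = second_src
    return values, provenance


def correct_series(
    series: ActivitySeries,
    log: EventLog,
    policy: PaddingPolicy | None = None,
    extra_intervals: Optional[Sequence[tuple[dt.datetime, dt.datetime]]] = None,
    context_minutes: int = 10,
    warn_removed_fraction: float = 0.5,
    max_removed_fraction: float = 0.9,
) -> CorrectedSeries:
    """Remove and impute all passive-movement spans of a recording.

    Composition of :func:`build_removal_intervals` and
    :func:`impute_interval`; imputation context never includes epochs of any
    removal interval. ``extra_intervals`` stands in for a manual screening
    pass. Raises :class:`UncorrectableSeriesError` when more than
    ``max_removed_fraction`` of the epochs would be removed (the situation in
    which a patient has hardly any activity left after cleaning and must be
    excluded); warns above ``warn_removed_fraction``.
    """
    intervals = build_removal_intervals(
        log, policy, series, extra_intervals=extra_intervals
    )
    removed = np.zeros(series.n_epochs, dtype=bool)
    for iv in intervals:
        removed[iv.epoch_slice(series)] = True
    frac = float(removed.mean()) if removed.size else 0.0
    if frac > max_removed_fraction:
        raise UncorrectableSeriesError(
            f"uncorrectable series {series.patient_id!r}: {frac:.0%} of epochs "
            f"removed (limit {max_removed_fraction:.0%}); exclude this patient"
        )
    if frac > warn_removed_fraction:
        warnings.warn(
            f"{series.patient_id}: {frac:.0%} of epochs removed by correction",
            stacklevel=2,
        )
    values = series.values.copy()
    provenance = np.full(series.n_epochs, "none", dtype=object)
    for iv in intervals:
        sl = iv.epoch_slice(series)
        imputed, prov = impute_interval(
            series, iv, context_minutes=context_minutes, removed_mask=removed
        )
        values[sl] = imputed
        provenance[sl] = prov
    return CorrectedSeries(
        series=series.with_values(values),
        removed=removed,
        intervals=intervals,
        imputed_from=provenance,
    )


def removed_fraction_report(corrected: CorrectedSeries) -> dict:
    """Fraction of epochs removed overall and per contributing event type.

    Merged intervals are attributed to every event type that contributed to
    them, so per-type fractions can sum to more than the overall fraction.
    """
    n = corrected.removed.size
    per_type: dict[str, float] = {}
    if n:
        for etype in sorted(REMOVABLE_EVENT_TYPES, key=lambda t: t.value):
            count = 0
            for iv in corrected.intervals:
                if etype in iv.source_types:
                    sl = iv.epoch_slice(corrected.series)
                    count += sl.stop - sl.start
            if count:
                per_type[etype.value] = count / n
    return {"overall": corrected.removed_fraction, "per_type": per_type}
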