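"""Synthetic ward cohorts: endogenous rhythms plus scheduled passive care.

No public recording of this kind of cohort exists, so the package ships a
generator that emulates the measurement situation end to end: an immobile
patient produces a weak endogenous rest-activity rhythm (a truncated cosine
plus noise, minute epochs); the ward imposes a care schedule — nursing rounds,
therapies, visits — that moves the instrumented wrist passively and injects
additional activity into the recording; staff log those events on a bedside
tablet, pressing "start" a few minutes late. The generator returns the
recorded series, the endogenous ground truth, the (imperfect) event log and
the true event windows, so every stage of the correction and analysis can be
validated against ground truth.

The headline confound this reproduces: care follows the *24-h ward clock*
even when the patient's own rhythm free-runs (e.g. at 25 h), so uncorrected
recordings look more "circadian" than the patient is.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .types import (
    ActivitySeries,
    CohortTable,
    EventLog,
    EventRecord,
    EventType,
    PatientRecord,
    ValidationError,
)

__all__ = [
    "EndogenousRhythmSpec",
    "CareEventTemplate",
    "SimulatedPatient",
    "generate_patient",
    "generate_cohort",
    "GroupConfig",
    "CohortConfig",
    "default_care_templates",
    "default_cohort_config",
    "headline_bias_config",
]

DEFAULT_START = dt.datetime(2021, 3, 1, 0, 0)


@dataclass(frozen=True)
class EndogenousRhythmSpec:
    """The patient's own rest-activity rhythm.

    ``mesor`` (baseline level) and ``amplitude`` are in arbitrary activity
    units; ``period_hours`` is the endogenous period (24 for entrained, ~25
    for a free-running rhythm); ``acrophase_hours`` is the clock time of the
    first peak. Noise is either zero-truncated Gaussian (sd ``noise_sd``) or
    Poisson-like (counts drawn around the mean level). ``rhythm_present``
    False forces the amplitude to zero (an arrhythmic patient).
    """

    mesor: float
    amplitude: float
    period_hours: float = 24.0
    acrophase_hours: float = 15.0
    noise_sd: float = 0.0
    noise_family: str = "gaussian_truncated_at_zero"
    rhythm_present: bool = True

    def __post_init__(self) -> None:
        if self.mesor < 0 or self.amplitude < 0 or self.noise_sd < 0:
            raise ValidationError("mesor, amplitude and noise_sd must be nonnegative")
        if not 1.0 < self.period_hours < 48.0:
            raise ValidationError("period_hours must lie in (1, 48)")
        if self.noise_family not in ("gaussian_truncated_at_zero", "poisson_like"):
            raise ValidationError(f"unknown noise_family {self.noise_family!r}")
        if self.noise_family == "gaussian_truncated_at_zero" and self.amplitude > self.mesor:
            raise ValidationError(
                "amplitude must not exceed mesor for zero-truncated Gaussian noise"
            )

    @property
    def effective_amplitude(self) -> float:
        return self.amplitude if self.rhythm_present else 0.0


@dataclass(frozen=True)
class CareEventTemplate:
    """One recurring scheduled care event.

    Each day, with probability ``occurrence_probability_per_day``, an event
    of ``duration_minutes`` is instantiated at ``clock_time_hours`` plus
    Gaussian jitter; ``passive_amplitude`` activity units are added to the
    recording while it lasts, and the log entry's start is shifted late by
    ``log_start_latency_minutes`` (staff press the button after starting to
    handle the patient — the reason removal intervals are padded).
    """

    event_type: EventType
    clock_time_hours: float
    duration_minutes: float
    passive_amplitude: float
    jitter_sd_minutes: float = 0.0
    occurrence_probability_per_day: float = 1.0
    log_start_latency_minutes: float = 3.0

    def __post_init__(self) -> None:
        if self.duration_minutes <= 0:
            raise ValidationError("duration_minutes must be positive")
        if not 0.0 <= self.occurrence_probability_per_day <= 1.0:
            raise ValidationError("occurrence probability must be in [0, 1]")
        if self.passive_amplitude < 0 or self.jitter_sd_minutes < 0:
            raise ValidationError("amplitudes and jitter must be nonnegative")
        if self.log_start_latency_minutes < 0:
            raise ValidationError("log latency must be nonnegative")


@dataclass
class SimulatedPatient:
    """One generated recording with full ground truth."""

    recorded: ActivitySeries
    endogenous_truth: ActivitySeries
    log: EventLog
    true_spec: EndogenousRhythmSpec
    seed: int
    true_events: list[tuple[dt.datetime, dt.datetime, EventType]] = field(
        default_factory=list
    )


def default_care_templates() -> list[CareEventTemplate]:
    """A plausible ward day: three nursing rounds, morning therapy, visit.

    Durations, probabilities and intensities are placeholders for a typical
    long-term care schedule (no quantitative inventory of real care events
    is published); they are deliberately strong relative to patients'
    endogenous activity, as passive handling of a limb dwarfs the activity
    an immobile patient produces.
    """
    return [
        CareEventTemplate(EventType.NURSING, 7.5, 45.0, 60.0, jitter_sd_minutes=10.0),
        CareEventTemplate(EventType.NURSING, 12.5, 30.0, 60.0, jitter_sd_minutes=10.0),
        CareEventTemplate(EventType.NURSING, 19.5, 30.0, 60.0, jitter_sd_minutes=10.0),
        CareEventTemplate(
            EventType.THERAPY, 10.0, 30.0, 50.0, jitter_sd_minutes=10.0,
            occurrence_probability_per_day=5.0 / 7.0,
        ),
        CareEventTemplate(
            EventType.VISIT, 14.5, 60.0, 40.0, jitter_sd_minutes=15.0,
            occurrence_probability_per_day=0.8,
        ),
    ]


def generate_patient(
    spec: EndogenousRhythmSpec,
    templates: Sequence[CareEventTemplate],
    days: int = 7,
    seed: int = 0,
    patient_id: str = "SIM",
    start_time: dt.datetime = DEFAULT_START,
) -> SimulatedPatient:
    """Simulate one patient's minute-resolution recording.

    The endogenous value at minute ``t`` is
    ``max(0, mesor + A cos(2 pi (t - acrophase) / period) + noise)``; for
    each day and template the scheduled care event is instantiated with its
    stated probability, its passive activity added to the recorded series,
    and a log entry emitted with the start pressed late. Identical inputs
    and seed give bit-identical output.
    """
    if days < 2:
        raise ValidationError("need at least 2 days (two rhythm cycles) to analyse")
    rng = np.random.default_rng(seed)
    n = days * 1440
    start_clock_hours = (
        start_time.hour + start_time.minute / 60.0 + start_time.second / 3600.0
    )
    hours = start_clock_hours + np.arange(n) / 60.0
    mean = spec.mesor + spec.effective_amplitude * np.cos(
        2.0 * np.pi * (hours - spec.acrophase_hours) / spec.period_hours
    )
    if spec.noise_family == "poisson_like":
        endog = rng.poisson(np.maximum(mean, 0.0), size=n).astype(float)
    else:
        endog = np.maximum(mean + rng.normal(0.0, spec.noise_sd, size=n), 0.0)
        if spec.noise_sd == 0:
            endog = np.maximum(mean, 0.0)

    recorded = endog.copy()
    events: list[EventRecord] = []
    true_events: list[tuple[dt.datetime, dt.datetime, EventType]] = []
    for template in templates:
        for day in range(days):
            occurs = rng.random() < template.occurrence_probability_per_day
            jitter = (
                rng.normal(0.0, template.jitter_sd_minutes)
                if template.jitter_sd_minutes > 0
                else 0.0
            )
            if not occurs:
                continue
            start_min = day * 1440 + (template.clock_time_hours - start_clock_hours) % 24.0 * 60.0 + jitter
            end_min = start_min + template.duration_minutes
            i0 = max(int(np.ceil(start_min)), 0)
            i1 = min(int(np.ceil(end_min)), n)
            if i1 <= i0:
                continue
            recorded[i0:i1] += template.passive_amplitude
            true_start = start_time + dt.timedelta(minutes=float(start_min))
            true_end = start_time + dt.timedelta(minutes=float(end_min))
            true_events.append((true_start, true_end, template.event_type))
            logged_start = true_start + dt.timedelta(
                minutes=template.log_start_latency_minutes
            )
            if logged_start < true_end:
                events.append(
                    EventRecord(template.event_type, logged_start, true_end)
                )
    log = EventLog(patient_id=patient_id, events=events).sorted()
    true_events.sort(key=lambda e: e[0])
    return SimulatedPatient(
        recorded=ActivitySeries(patient_id, start_time, 60, recorded),
        endogenous_truth=ActivitySeries(patient_id, start_time, 60, endog),
        log=log,
        true_spec=spec,
        seed=seed,
        true_events=true_events,
    )


@dataclass(frozen=True)
class GroupConfig:
    """Distribution of endogenous rhythm parameters within one cohort group.

    Ranges are uniform draw bounds per patient.
    """

    n: int
    mesor: tuple[float, float]
    amplitude: tuple[float, float]
    noise_sd: tuple[float, float]
    period_hours: float = 24.0
    acrophase: tuple[float, float] = (13.0, 17.0)
    crs_r: tuple[int, int] = (1, 8)
    diagnoses: tuple[str, ...] = ("UWS",)

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValidationError("each group needs at least one patient")


@dataclass(frozen=True)
class CohortConfig:
    groups: dict[str, GroupConfig]
    days: int = 7
    templates: Sequence[CareEventTemplate] = field(default_factory=default_care_templates)

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValidationError("cohort needs at least one group")


def default_cohort_config(n_uws: int = 3, n_mcs_emcs: int = 3, days: int = 7) -> CohortConfig:
    """Entrained 24-h cohort: conscious patients move more and more rhythmically."""
    return CohortConfig(
        groups={
            "UWS": GroupConfig(
                n=n_uws, mesor=(5.0, 10.0), amplitude=(0.5, 2.5),
                noise_sd=(3.0, 6.0), crs_r=(1, 8), diagnoses=("UWS",),
            ),
            "MCS_EMCS": GroupConfig(
                n=n_mcs_emcs, mesor=(12.0, 25.0), amplitude=(5.0, 12.0),
                noise_sd=(4.0, 8.0), crs_r=(8, 23), diagnoses=("MCS", "EMCS"),
            ),
        },
        days=days,
    )


def headline_bias_config(n_patients: int = 20, days: int = 7) -> CohortConfig:
    """The bias scenario: weak free-running 25-h rhythms, 24-h care schedule.

    Every patient's endogenous rhythm deviates a full hour from 24 h, so a
    faithful analysis must classify them non-circadian; the ward schedule
    repeats on the 24-h clock and, uncorrected, masquerades as an entrained
    circadian rhythm.
    """
    half = n_patients // 2
    return CohortConfig(
        groups={
            "UWS": GroupConfig(
                n=n_patients - half, mesor=(8.0, 12.0), amplitude=(2.0, 4.0),
                noise_sd=(3.0, 5.0), period_hours=25.0, crs_r=(1, 8),
            ),
            "MCS_EMCS": GroupConfig(
                n=half, mesor=(10.0, 16.0), amplitude=(3.0, 6.0),
                noise_sd=(3.0, 5.0), period_hours=25.0, crs_r=(8, 23),
                diagnoses=("MCS", "EMCS"),
            ),
        },
        days=days,
    )


def generate_cohort(
    config: CohortConfig, seed: int = 0
) -> tuple[list[SimulatedPatient], CohortTable]:
    """Simulate a cohort of patients plus matching clinical metadata.

    Patient-level rhythm parameters are drawn from the group distributions;
    each patient then gets an independent child seed for the recording, so
    the whole cohort is deterministic under ``seed``.
    """
    rng = np.random.default_rng(seed)
    patients: list[SimulatedPatient] = []
    records: list[PatientRecord] = []
    idx = 0
    for group_name, group in config.groups.items():
        for k in range(group.n):
            idx += 1
            pid = f"SIM{idx:02d}"
            spec = EndogenousRhythmSpec(
                mesor=float(rng.uniform(*group.mesor)),
                amplitude=float(rng.uniform(*group.amplitude)),
                period_hours=group.period_hours,
                acrophase_hours=float(rng.uniform(*group.acrophase)),
                noise_sd=float(rng.uniform(*group.noise_sd)),
            )
            child_seed = int(rng.integers(0, 2**31 - 1))
            patients.append(
                generate_patient(
                    spec,
                    config.templates,
                    days=config.days,
                    seed=child_seed,
                    patient_id=pid,
                )
            )
            records.append(
                PatientRecord(
                    patient_id=pid,
                    age=float(np.round(rng.uniform(19, 78))),
                    sex="F" if rng.random() < 0.5 else "M",
                    etiology="TBI" if rng.random() < 0.4 else "NTBI",
                    months_since_injury=float(np.round(rng.uniform(1.5, 200.0), 1)),
                    diagnosis=group.diagnoses[k % len(group.diagnoses)],
                    crs_r_sum=int(rng.integers(group.crs_r[0], group.crs_r[1] + 1)),
                )
            )
    return patients, CohortTable(records)
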