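import datetime as dt

import numpy as np
import pytest

from actirhythm import ActivitySeries

MIDNIGHT = dt.datetime(2021, 3, 1, 0, 0)


def make_series(
    values,
    start=MIDNIGHT,
    epoch_seconds=60,
    patient_id="T",
):
    return ActivitySeries(patient_id, start, epoch_seconds, np.asarray(values, dtype=float))


def sine_series(
    days=7,
    period_hours=24.0,
    mesor=10.0,
    amplitude=5.0,
    acrophase_hours=14.0,
    epoch_minutes=1,
    noise_sd=0.0,
    seed=0,
    start=MIDNIGHT,
):
    """Cosine-plus-noise series starting at local midnight."""
    n = days * 1440 // epoch_minutes
    hours = np.arange(n) * epoch_minutes / 60.0
    values = mesor + amplitude * np.cos(2 * np.pi * (hours - acrophase_hours) / period_hours)
    if noise_sd:
        values = values + np.random.default_rng(seed).normal(0, noise_sd, n)
    return make_series(np.maximum(values, 0.0), start=start, epoch_seconds=epoch_minutes * 60)


@pytest.fixture
def midnight():
    return MIDNIGHT
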