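import numpy as np
import pandas as pd
import pytest

import cgmeval as cg

T0 = pd.Timestamp("2024-03-01 08:00")
MIN = pd.Timedelta(minutes=1)


def make_session(
    minutes,
    values=None,
    init=T0,
    removal=None,
    sensor_id="S1",
    patient_id="P1",
    calibrations=(),
):
    """Session with samples at the given minute offsets from init."""
    minutes = list(minutes)
    if values is None:
        values = [120.0] * len(minutes)
    samples = [
        cg.GlucoseSample(init + m * MIN, v, cg.Source.SENSOR, patient_id)
        for m, v in zip(minutes, values)
    ]
    if removal is None:
        removal = init + (minutes[-1] if minutes else 0) * MIN
    return cg.SensorSession(
        sensor_id=sensor_id,
        patient_id=patient_id,
        init_time=init,
        samples=samples,
        calibrations=[cg.CalibrationEvent(init + m * MIN, v) for m, v in calibrations],
        removal_time=removal,
    )


def make_pairs(values, patient_id="P1"):
    """PairedReadings from (reference, sensor) tuples, one minute apart."""
    return [
        cg.PairedReading.make(patient_id, "S1", T0 + i * MIN, r, s, "arterial")
        for i, (r, s) in enumerate(values)
    ]


def minute_series(values, start=T0, step_min=1):
    idx = pd.date_range(start, periods=len(values), freq=f"{step_min}min")
    return pd.Series(list(values), index=idx)


@pytest.fixture(scope="session")
def noiseless_cohort():
    """Small noise-free, lag-free, gap-free cohort: sensor == blood."""
    return cg.generate_cohort(cg.noiseless_config(n_patients=6, seed=3))


@pytest.fixture(scope="session")
def default_cohort():
    """Small cohort at the default (study-condition) generator settings."""
    return cg.generate_cohort(cg.SimulationConfig(n_patients=6, seed=5))


@pytest.fixture(scope="session")
def default_pairs(default_cohort):
    return cg.extract_all_pairs(default_cohort.records).pairs
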