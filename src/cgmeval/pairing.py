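"""Comparative reference/sensor pair extraction.

Point accuracy is evaluated on pairs of one reference blood-glucose value
and the latest sensor value at or before it. Reference values that served
as initial calibrations (start-up, +1 h, +2 h) or as recalibrations after a
display gap longer than 15 min are excluded; routine 8-hourly calibration
values are paired but flagged so they can be filtered. A reference is
unpairable when no sensor value exists within the pairing window (default
5 min) before it, e.g. during a display gap.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_model import (
    CalibrationEvent,
    CalibrationKind,
    PatientRecord,
    SensorSession,
)

#: sensor value must be at most this many minutes before the reference draw
DEFAULT_PAIRING_WINDOW_MIN = 5
#: a display gap longer than this immediately before a calibration makes it post_gap
POST_GAP_THRESHOLD_MIN = 15
#: tolerance for matching a reference draw to a calibration event
CALIBRATION_MATCH_TOLERANCE_MIN = 1
#: number of start-up calibrations (start, ~+1 h, ~+2 h) excluded from accuracy
N_INITIAL_CALIBRATIONS = 3

MIN_MONITORED_HOURS = 48.0
MIN_COMPARATIVE_READINGS = 12


def ard(reference: float, sensor: float) -> float:
    """Absolute relative difference |reference - sensor| / reference * 100."""
    return abs(reference - sensor) / reference * 100.0


@dataclass(frozen=True)
class PairedReading:
    patient_id: str
    sensor_id: str
    timestamp: pd.Timestamp
    reference_value: float
    sensor_value: float
    ard: float
    reference_source: str
    is_calibration: bool = False  # scheduled-calibration reference, filterable

    @staticmethod
    def make(
        patient_id: str,
        sensor_id: str,
        timestamp: pd.Timestamp,
        reference_value: float,
        sensor_value: float,
        reference_source: str,
        is_calibration: bool = False,
    ) -> "PairedReading":
        return PairedReading(
            patient_id,
            sensor_id,
            timestamp,
            reference_value,
            sensor_value,
            ard(reference_value, sensor_value),
            reference_source,
            is_calibration,
        )


@dataclass
class PairExtraction:
    """Pairs plus the bookkeeping of what happened to every reference."""

    pairs: list[PairedReading]
    n_references: int
    n_excluded_calibration: int  # initial or post-gap calibration values
    n_unpairable: int            # no sensor value within the window
    n_outside_sessions: int      # reference outside any monitoring span

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "patient_id": p.patient_id,
                    "sensor_id": p.sensor_id,
                    "timestamp": p.timestamp,
                    "reference_mgdl": p.reference_value,
                    "sensor_mgdl": p.sensor_value,
                    "ard_pct": p.ard,
                    "source": p.reference_source,
                    "is_calibration": p.is_calibration,
                }
                for p in self.pairs
            ]
        )


@dataclass(frozen=True)
class InclusionDecision:
    patient_id: str
    monitored_hours: float
    n_pairs: int
    included: bool
    reason: str


def classify_calibration(event: CalibrationEvent, session: SensorSession) -> CalibrationKind:
    """Assign initial / post_gap / scheduled to one calibration event.

    The first three calibrations of a session (start-up and the entries
    after the first and second running hour) are *initial*, identified by
    order. A calibration preceded by a display gap of more than 15 min is
    *post_gap*. Everything else is a routine *scheduled* calibration.
    """
    if not (session.init_time <= event.timestamp <= session.end_time):
        raise ValueError(
            f"calibration at {event.timestamp} outside session "
            f"[{session.init_time}, {session.end_time}]"
        )
    ordered = sorted(session.calibrations, key=lambda c: c.timestamp)
    times = [c.timestamp for c in ordered]
    if event.timestamp in times[:N_INITIAL_CALIBRATIONS]:
        return CalibrationKind.INITIAL
    sample_times = session.sample_times()
    before = sample_times[sample_times < event.timestamp]
    if len(before) == 0:
        missing_min = (event.timestamp - session.init_time) / pd.Timedelta(minutes=1)
    else:
        # consecutive displayed minutes differ by 1; anything beyond is gap
        missing_min = (event.timestamp - before[-1]) / pd.Timedelta(minutes=1) - 1
    if missing_min > POST_GAP_THRESHOLD_MIN:
        return CalibrationKind.POST_GAP
    return CalibrationKind.SCHEDULED


def classify_session_calibrations(session: SensorSession) -> list[CalibrationEvent]:
    """Return the session's calibrations with kinds filled in, time-ordered."""
    ordered = sorted(session.calibrations, key=lambda c: c.timestamp)
    return [
        CalibrationEvent(c.timestamp, c.reference_value, classify_calibration(c, session))
        for c in ordered
    ]


def extract_pairs(
    record: PatientRecord, window_min: int = DEFAULT_PAIRING_WINDOW_MIN
) -> PairExtraction:
    """Extract the comparative pairs for one patient.

    Ties at the same minute use the same-minute sensor value ("immediately
    before" at minute resolution includes the minute itself). References
    with no running session are counted but never paired; they remain
    available to the glycemic-metrics analyses.
    """
    window = pd.Timedelta(minutes=window_min)
    excluded_minutes: dict[str, set[pd.Timestamp]] = {}
    scheduled_minutes: dict[str, set[pd.Timestamp]] = {}
    tol = pd.Timedelta(minutes=CALIBRATION_MATCH_TOLERANCE_MIN)
    for session in record.sessions:
        exc, sch = set(), set()
        for cal in classify_session_calibrations(session):
            target = exc if cal.kind in (CalibrationKind.INITIAL, CalibrationKind.POST_GAP) else sch
            t = cal.timestamp
            step = pd.Timedelta(minutes=1)
            k = -int(tol / step)
            while k <= int(tol / step):
                target.add(t + k * step)
                k += 1
        excluded_minutes[session.sensor_id] = exc
        scheduled_minutes[session.sensor_id] = sch

    pairs: list[PairedReading] = []
    n_excl = n_unpair = n_outside = 0
    for ref in record.reference_samples:
        active = [
            s for s in record.sessions if s.init_time <= ref.timestamp <= s.end_time
        ]
        if not active:
            n_outside += 1
            continue
        if any(ref.timestamp in excluded_minutes[s.sensor_id] for s in active):
            n_excl += 1
            continue
        best: tuple[pd.Timestamp, float, str] | None = None
        for session in active:
            times = session.sample_times()
            idx = times.searchsorted(ref.timestamp, side="right") - 1
            if idx < 0:
                continue
            t = times[idx]
            if ref.timestamp - t > window:
                continue
            if best is None or t > best[0]:
                best = (t, session.samples[idx].value, session.sensor_id)
        if best is None:
            n_unpair += 1
            continue
        pairs.append(
            PairedReading.make(
                record.patient_id,
                best[2],
                ref.timestamp,
                ref.value,
                best[1],
                ref.source.value,
                is_calibration=any(
                    ref.timestamp in scheduled_minutes[s.sensor_id] for s in active
                ),
            )
        )
    return PairExtraction(pairs, len(record.reference_samples), n_excl, n_unpair, n_outside)


def extract_all_pairs(
    records: Mapping[str, PatientRecord], window_min: int = DEFAULT_PAIRING_WINDOW_MIN
) -> PairExtraction:
    """Pool pair extraction over a cohort, keeping the bookkeeping totals."""
    pairs: list[PairedReading] = []
    n_ref = n_excl = n_unpair = n_outside = 0
    for pid in sorted(records):
        ext = extract_pairs(records[pid], window_min)
        pairs.extend(ext.pairs)
        n_ref += ext.n_references
        n_excl += ext.n_excluded_calibration
        n_unpair += ext.n_unpairable
        n_outside += ext.n_outside_sessions
    return PairExtraction(pairs, n_ref, n_excl, n_unpair, n_outside)


def apply_inclusion(
    records: Mapping[str, PatientRecord],
    pairs: Iterable[PairedReading] | None = None,
    window_min: int = DEFAULT_PAIRING_WINDOW_MIN,
) -> list[InclusionDecision]:
    """Accuracy-analysis inclusion: >=48 monitored hours OR >=12 pairs."""
    if pairs is None:
        pairs = extract_all_pairs(records, window_min).pairs
    n_by_patient: dict[str, int] = {}
    for p in pairs:
        n_by_patient[p.patient_id] = n_by_patient.get(p.patient_id, 0) + 1
    decisions = []
    for pid in sorted(records):
        hours = records[pid].monitoring_hours
        n = n_by_patient.get(pid, 0)
        included = hours >= MIN_MONITORED_HOURS or n >= MIN_COMPARATIVE_READINGS
        if hours >= MIN_MONITORED_HOURS:
            reason = f"monitored {hours:.1f} h >= 48 h"
        elif n >= MIN_COMPARATIVE_READINGS:
            reason = f"{n} comparative readings >= 12"
        else:
            reason = f"only {hours:.1f} h and {n} readings"
        decisions.append(InclusionDecision(pid, hours, n, included, reason))
    return decisions
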