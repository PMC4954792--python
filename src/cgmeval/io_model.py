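"""Domain types, CSV readers/writers and session validation.

The data model mirrors how ICU CGM evaluations are organised: per-minute
sensor traces grouped into sensor sessions (up to 72 h each), intermittent
reference blood-gas glucose values (arterial or venous), calibration events
that re-anchor the sensor, and optional per-timestamp clinical covariates.

All glucose values are mg/dl; timestamps are handled at 1-minute resolution
(the device emits one value per minute) — sub-minute input is floored with a
warning. Missing minutes inside a session are represented by absence, never
by sentinel values; gap detection is a downstream computation.
"""

from __future__ import annotations

import enum
import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

HOURS_72 = pd.Timedelta(hours=72)
#: slack allowed on the 72-h session limit (scheduling jitter)
SESSION_SPAN_TOLERANCE = pd.Timedelta(minutes=30)


class Source(str, enum.Enum):
    """Origin of a glucose value."""

    SENSOR = "sensor"
    ARTERIAL = "arterial"
    VENOUS = "venous"


class CalibrationKind(str, enum.Enum):
    INITIAL = "initial"        # start-up entry and the +1 h / +2 h entries
    SCHEDULED = "scheduled"    # routine 8-hourly calibration
    POST_GAP = "post_gap"      # calibration after a display gap > 15 min


def _floor_minute(ts: pd.Timestamp) -> pd.Timestamp:
    floored = ts.floor("min")
    if floored != ts:
        warnings.warn(f"sub-minute timestamp {ts} floored to {floored}", stacklevel=3)
    return floored


@dataclass(frozen=True)
class GlucoseSample:
    """One timestamped glucose value with its source tag."""

    timestamp: pd.Timestamp
    value: float
    source: Source
    patient_id: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "timestamp", _floor_minute(pd.Timestamp(self.timestamp)))
        object.__setattr__(self, "source", Source(self.source))
        if not (self.value > 0 and self.value == self.value and self.value != float("inf")):
            raise ValueError(f"glucose value must be positive and finite, got {self.value!r}")


@dataclass(frozen=True)
class CalibrationEvent:
    """A reference blood-glucose entry used to calibrate the sensor."""

    timestamp: pd.Timestamp
    reference_value: float
    kind: CalibrationKind | None = None  # assigned by pairing.classify_calibration

    def __post_init__(self) -> None:
        object.__setattr__(self, "timestamp", _floor_minute(pd.Timestamp(self.timestamp)))
        if self.kind is not None:
            object.__setattr__(self, "kind", CalibrationKind(self.kind))
        if not self.reference_value > 0:
            raise ValueError("calibration reference_value must be > 0")


@dataclass
class SensorSession:
    """One sensor's per-minute trace with its calibrations and removal record.

    ``removal_cause`` uses the 7-code taxonomy for premature removals
    (1 accidental, 2 poor signal during measurement, 3 poor signal after
    initialization, 4 MRI, 5 discharge, 6 death, 7 other); codes 1-3 are
    device-related. ``gap_causes`` optionally maps a gap's first missing
    minute to the analogous 7-code gap-cause taxonomy.
    """

    sensor_id: str
    patient_id: str
    init_time: pd.Timestamp
    samples: list[GlucoseSample]
    calibrations: list[CalibrationEvent] = field(default_factory=list)
    removal_time: pd.Timestamp | None = None
    removal_cause: int | None = None
    gap_causes: dict[pd.Timestamp, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.init_time = _floor_minute(pd.Timestamp(self.init_time))
        if self.removal_time is not None:
            self.removal_time = _floor_minute(pd.Timestamp(self.removal_time))

    @property
    def end_time(self) -> pd.Timestamp:
        if self.removal_time is not None:
            return self.removal_time
        return self.samples[-1].timestamp if self.samples else self.init_time

    @property
    def monitoring_minutes(self) -> int:
        """Actual monitoring span init -> removal, in whole minutes."""
        return int((self.end_time - self.init_time) / pd.Timedelta(minutes=1)) + 1

    def sample_times(self) -> pd.DatetimeIndex:
        return pd.DatetimeIndex([s.timestamp for s in self.samples])

    def to_series(self) -> pd.Series:
        """Per-minute trace as a float Series indexed by timestamp."""
        return pd.Series(
            [s.value for s in self.samples], index=self.sample_times(), name=self.sensor_id
        )


@dataclass
class PatientRecord:
    """All data for one patient: sessions, reference draws, covariates."""

    patient_id: str
    sessions: list[SensorSession]
    reference_samples: list[GlucoseSample]
    covariates: pd.DataFrame | None = None  # columns: timestamp, name, value

    def reference_series(self) -> pd.Series:
        ordered = sorted(self.reference_samples, key=lambda s: s.timestamp)
        return pd.Series(
            [s.value for s in ordered],
            index=pd.DatetimeIndex([s.timestamp for s in ordered]),
        )

    @property
    def monitoring_hours(self) -> float:
        return sum(s.monitoring_minutes for s in self.sessions) / 60.0


class DatasetError(ValueError):
    """Malformed or inconsistent input data."""


def validate_session(session: SensorSession) -> list[str]:
    """Check session invariants; returns one message per violation.

    An empty list means the session is well-formed: strictly increasing
    sample times, samples within [init_time, removal_time], span at most
    72 h (plus scheduling tolerance), positive values (enforced at
    construction) and calibrations inside the monitoring span.
    """
    violations: list[str] = []
    times = session.sample_times()
    if len(times) and not times.is_monotonic_increasing:
        violations.append("sample timestamps are not increasing")
    if times.has_duplicates:
        dup = times[times.duplicated()][0]
        violations.append(f"duplicate sample timestamp {dup}")
    if len(times):
        if times[0] < session.init_time:
            violations.append(f"first sample {times[0]} precedes init_time {session.init_time}")
        if session.removal_time is not None and times[-1] > session.removal_time:
            violations.append(
                f"last sample {times[-1]} is after removal_time {session.removal_time}"
            )
    span = session.end_time - session.init_time
    if span > HOURS_72 + SESSION_SPAN_TOLERANCE:
        violations.append(f"session span {span} exceeds 72 h")
    if session.removal_cause is not None and session.removal_cause not in range(1, 8):
        violations.append(f"removal_cause {session.removal_cause} outside 1-7")
    for cal in session.calibrations:
        if not (session.init_time <= cal.timestamp <= session.end_time):
            violations.append(f"calibration at {cal.timestamp} outside session span")
    return violations


# ---------------------------------------------------------------------------
# CSV dialect
# ---------------------------------------------------------------------------

CGM_COLUMNS = ["patient_id", "sensor_id", "timestamp", "glucose_mgdl"]
REFERENCE_COLUMNS = ["patient_id", "timestamp", "glucose_mgdl", "source"]
CALIBRATION_COLUMNS = ["patient_id", "sensor_id", "timestamp", "reference_mgdl"]
SESSION_COLUMNS = ["patient_id", "sensor_id", "init_time", "removal_time", "removal_cause"]
COVARIATE_COLUMNS = ["patient_id", "timestamp", "name", "value"]


def _read_csv(path: str | Path, columns: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise DatasetError(f"input file not found: {path}")
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise DatasetError(f"{path}: missing columns {missing}")
    return df


def _parse_times(df: pd.DataFrame, column: str, path: str) -> pd.Series:
    try:
        return pd.to_datetime(df[column], format="ISO8601")
    except (ValueError, TypeError):
        parsed = pd.to_datetime(df[column], format="ISO8601", errors="coerce")
        bad = parsed.isna() & df[column].notna()
        row = int(bad.idxmax()) + 2  # header is line 1
        raise DatasetError(
            f"{path}: malformed timestamp {df[column][bad.idxmax()]!r} at line {row}"
        ) from None


def load_dataset(
    cgm_path: str | Path,
    reference_path: str | Path,
    calibration_path: str | Path,
    sessions_path: str | Path,
    covariate_path: str | Path | None = None,
) -> dict[str, PatientRecord]:
    """Assemble PatientRecords from the CSV dialect.

    Every row is either parsed into the model or raises a DatasetError that
    names the offending row — rows are never silently dropped.
    """
    cgm = _read_csv(cgm_path, CGM_COLUMNS)
    cgm["timestamp"] = _parse_times(cgm, "timestamp", str(cgm_path))
    cgm["glucose_mgdl"] = cgm["glucose_mgdl"].astype(float)
    dup = cgm.duplicated(subset=["sensor_id", "timestamp"])
    if dup.any():
        i = int(dup.idxmax())
        raise DatasetError(
            f"{cgm_path}: duplicate (sensor_id, timestamp) "
            f"({cgm['sensor_id'][i]}, {cgm['timestamp'][i]}) at line {i + 2}"
        )

    ref = _read_csv(reference_path, REFERENCE_COLUMNS)
    ref["timestamp"] = _parse_times(ref, "timestamp", str(reference_path))
    ref["glucose_mgdl"] = ref["glucose_mgdl"].astype(float)
    bad_src = ~ref["source"].isin([Source.ARTERIAL.value, Source.VENOUS.value])
    if bad_src.any():
        i = int(bad_src.idxmax())
        raise DatasetError(
            f"{reference_path}: unknown source tag {ref['source'][i]!r} at line {i + 2}"
        )

    cal = _read_csv(calibration_path, CALIBRATION_COLUMNS)
    cal["timestamp"] = _parse_times(cal, "timestamp", str(calibration_path))
    cal["reference_mgdl"] = cal["reference_mgdl"].astype(float)

    ses = _read_csv(sessions_path, SESSION_COLUMNS)
    ses["init_time"] = _parse_times(ses, "init_time", str(sessions_path))
    ses["removal_time"] = _parse_times(ses, "removal_time", str(sessions_path))

    cov = None
    if covariate_path is not None:
        cov = _read_csv(covariate_path, COVARIATE_COLUMNS)
        cov["timestamp"] = _parse_times(cov, "timestamp", str(covariate_path))
        cov["value"] = cov["value"].astype(float)

    records: dict[str, PatientRecord] = {}
    cgm_by_sensor = dict(tuple(cgm.groupby("sensor_id", sort=False)))
    cal_by_sensor = dict(tuple(cal.groupby("sensor_id", sort=False)))
    for _, row in ses.iterrows():
        pid, sid = row["patient_id"], row["sensor_id"]
        trace = cgm_by_sensor.get(sid, pd.DataFrame(columns=CGM_COLUMNS)).sort_values("timestamp")
        samples = [
            GlucoseSample(t, v, Source.SENSOR, pid)
            for t, v in zip(trace["timestamp"], trace["glucose_mgdl"])
        ]
        cals = cal_by_sensor.get(sid, pd.DataFrame(columns=CALIBRATION_COLUMNS)).sort_values(
            "timestamp"
        )
        session = SensorSession(
            sensor_id=sid,
            patient_id=pid,
            init_time=row["init_time"],
            samples=samples,
            calibrations=[
                CalibrationEvent(t, v) for t, v in zip(cals["timestamp"], cals["reference_mgdl"])
            ],
            removal_time=row["removal_time"],
            removal_cause=int(row["removal_cause"]) if pd.notna(row["removal_cause"]) else None,
        )
        problems = validate_session(session)
        if problems:
            raise DatasetError(f"session {sid}: " + "; ".join(problems))
        records.setdefault(pid, PatientRecord(pid, [], [])).sessions.append(session)

    for _, row in ref.iterrows():
        pid = row["patient_id"]
        rec = records.setdefault(pid, PatientRecord(pid, [], []))
        rec.reference_samples.append(
            GlucoseSample(row["timestamp"], row["glucose_mgdl"], Source(row["source"]), pid)
        )
    for rec in records.values():
        rec.reference_samples.sort(key=lambda s: s.timestamp)
        rec.sessions.sort(key=lambda s: s.init_time)

    if cov is not None:
        for pid, grp in cov.groupby("patient_id", sort=False):
            if pid in records:
                records[pid].covariates = (
                    grp[["timestamp", "name", "value"]].sort_values("timestamp").reset_index(drop=True)
                )
    return records


def save_bundle(records: Mapping[str, PatientRecord], path: str | Path) -> None:
    """Serialize a validated dataset to one JSON bundle (CLI hand-off format)."""
    doc: dict = {"patients": {}}
    for pid in sorted(records):
        rec = records[pid]
        doc["patients"][pid] = {
            "sessions": [
                {
                    "sensor_id": s.sensor_id,
                    "init_time": s.init_time.isoformat(),
                    "removal_time": s.end_time.isoformat(),
                    "removal_cause": s.removal_cause,
                    "samples": [[x.timestamp.isoformat(), x.value] for x in s.samples],
                    "calibrations": [
                        [c.timestamp.isoformat(), c.reference_value] for c in s.calibrations
                    ],
                    "gap_causes": {t.isoformat(): c for t, c in s.gap_causes.items()},
                }
                for s in rec.sessions
            ],
            "reference": [
                [x.timestamp.isoformat(), x.value, x.source.value]
                for x in rec.reference_samples
            ],
            "covariates": None
            if rec.covariates is None
            else [
                [r["timestamp"].isoformat(), r["name"], r["value"]]
                for _, r in rec.covariates.iterrows()
            ],
        }
    Path(path).write_text(json.dumps(doc))


def load_bundle(path: str | Path) -> dict[str, PatientRecord]:
    doc = json.loads(Path(path).read_text())
    records: dict[str, PatientRecord] = {}
    for pid, p in doc["patients"].items():
        sessions = [
            SensorSession(
                sensor_id=s["sensor_id"],
                patient_id=pid,
                init_time=pd.Timestamp(s["init_time"]),
                samples=[
                    GlucoseSample(pd.Timestamp(t), v, Source.SENSOR, pid)
                    for t, v in s["samples"]
                ],
                calibrations=[
                    CalibrationEvent(pd.Timestamp(t), v) for t, v in s["calibrations"]
                ],
                removal_time=pd.Timestamp(s["removal_time"]),
                removal_cause=s["removal_cause"],
                gap_causes={pd.Timestamp(t): c for t, c in s["gap_causes"].items()},
            )
            for s in p["sessions"]
        ]
        cov = None
        if p["covariates"] is not None:
            cov = pd.DataFrame(p["covariates"], columns=["timestamp", "name", "value"])
            cov["timestamp"] = pd.to_datetime(cov["timestamp"])
        records[pid] = PatientRecord(
            patient_id=pid,
            sessions=sessions,
            reference_samples=[
                GlucoseSample(pd.Timestamp(t), v, Source(src), pid)
                for t, v, src in p["reference"]
            ],
            covariates=cov,
        )
    return records


def write_dataset(records: Mapping[str, PatientRecord], out_dir: str | Path) -> dict[str, Path]:
    """Write records back to the CSV dialect. Inverse of load_dataset."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cgm_rows, ref_rows, cal_rows, ses_rows, cov_rows = [], [], [], [], []
    for pid in sorted(records):
        rec = records[pid]
        for session in rec.sessions:
            for s in session.samples:
                cgm_rows.append((pid, session.sensor_id, s.timestamp.isoformat(), s.value))
            for c in session.calibrations:
                cal_rows.append((pid, session.sensor_id, c.timestamp.isoformat(), c.reference_value))
            ses_rows.append(
                (
                    pid,
                    session.sensor_id,
                    session.init_time.isoformat(),
                    session.end_time.isoformat(),
                    session.removal_cause if session.removal_cause is not None else "",
                )
            )
        for s in rec.reference_samples:
            ref_rows.append((pid, s.timestamp.isoformat(), s.value, s.source.value))
        if rec.covariates is not None:
            for _, row in rec.covariates.iterrows():
                cov_rows.append((pid, row["timestamp"].isoformat(), row["name"], row["value"]))

    paths = {
        "cgm": out / "cgm.csv",
        "reference": out / "reference.csv",
        "calibrations": out / "calibrations.csv",
        "sessions": out / "sessions.csv",
    }
    pd.DataFrame(cgm_rows, columns=CGM_COLUMNS).to_csv(paths["cgm"], index=False)
    pd.DataFrame(ref_rows, columns=REFERENCE_COLUMNS).to_csv(paths["reference"], index=False)
    pd.DataFrame(cal_rows, columns=CALIBRATION_COLUMNS).to_csv(paths["calibrations"], index=False)
    pd.DataFrame(ses_rows, columns=SESSION_COLUMNS).to_csv(paths["sessions"], index=False)
    if cov_rows:
        paths["covariates"] = out / "covariates.csv"
        pd.DataFrame(cov_rows, columns=COVARIATE_COLUMNS).to_csv(paths["covariates"], index=False)
    return paths
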