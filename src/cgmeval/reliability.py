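"""Display-gap detection, gap taxonomy and reliability summaries.

A gap is any run of missing minutes inside a sensor session's monitoring
span; truncation at the end of a session is a (possibly premature) removal,
not a gap. Gaps are categorized by duration — very brief (< 15 min), brief
(15-30 min), prolonged (31-120 min), very prolonged (> 120 min) — and
attributed to annotated cause codes 1-7, of which 1-3 (poor sensor signal,
sensor failure, processor line error) count as device-related.

The consensus reliability criterion asks for real-time display during
> 95 % of time with device-related gaps shorter than 30 min; the display
share is evaluated against actual monitoring time by default (expected
72 h is available as the alternative denominator, and both appear in the
cohort summary).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_model import PatientRecord, SensorSession

EXPECTED_MINUTES = 72 * 60
DEVICE_RELATED_CODES = frozenset({1, 2, 3})

GAP_CAUSE_LABELS = {
    1: "poor sensor signal",
    2: "sensor failure",
    3: "processor line error",
    4: "disconnection",
    5: "pending after reconnection",
    6: "calibration required",
    7: "others",
}

REMOVAL_CAUSE_LABELS = {
    1: "accidentally",
    2: "poor sensor signal during measurement",
    3: "poor sensor signal immediately after initialization",
    4: "MRI",
    5: "discharge",
    6: "death",
    7: "others",
}


class GapCategory(str, enum.Enum):
    VERY_BRIEF = "very_brief"        # < 15 min
    BRIEF = "brief"                  # 15-30 min inclusive
    PROLONGED = "prolonged"          # 31-120 min
    VERY_PROLONGED = "very_prolonged"  # > 120 min


#: upper edges (inclusive) of the first three categories, in minutes
CATEGORY_EDGES = {"very_brief": 14, "brief": 30, "prolonged": 120}


def classify_gap(duration_min: int) -> GapCategory:
    if duration_min < 1:
        raise ValueError("gap duration must be >= 1 minute")
    if duration_min <= CATEGORY_EDGES["very_brief"]:
        return GapCategory.VERY_BRIEF
    if duration_min <= CATEGORY_EDGES["brief"]:
        return GapCategory.BRIEF
    if duration_min <= CATEGORY_EDGES["prolonged"]:
        return GapCategory.PROLONGED
    return GapCategory.VERY_PROLONGED


@dataclass(frozen=True)
class GapRecord:
    sensor_id: str
    start: pd.Timestamp       # first missing minute
    end: pd.Timestamp         # last missing minute
    duration_min: int
    category: GapCategory
    cause_code: int | None = None

    @property
    def device_related(self) -> bool:
        return self.cause_code in DEVICE_RELATED_CODES


def detect_gaps(session: SensorSession) -> list[GapRecord]:
    """Find every run of missing display minutes inside the session.

    Missing minutes between init_time and the first sample count as a gap
    (the display was expected from init onwards); minutes after the last
    sample up to removal are treated as part of the removal, not a gap,
    unless samples resume — by construction they cannot.
    """
    minute = pd.Timedelta(minutes=1)
    times = session.sample_times()
    gaps: list[GapRecord] = []

    def add(start: pd.Timestamp, end: pd.Timestamp) -> None:
        dur = int((end - start) / minute) + 1
        gaps.append(
            GapRecord(
                session.sensor_id,
                start,
                end,
                dur,
                classify_gap(dur),
                session.gap_causes.get(start),
            )
        )

    if len(times) == 0:
        return gaps
    if times[0] > session.init_time:
        add(session.init_time, times[0] - minute)
    diffs = (times[1:] - times[:-1]) / minute
    for i in np.nonzero(np.asarray(diffs) > 1)[0]:
        add(times[i] + minute, times[i + 1] - minute)
    return gaps


@dataclass
class SensorReliability:
    sensor_id: str
    expected_minutes: int
    actual_monitoring_minutes: int
    displayed_minutes: int
    gap_minutes: int
    pct_display_of_expected: float
    pct_display_of_actual: float
    n_gaps: int
    n_calibrations: int


@dataclass
class ReliabilityReport:
    """Per-sensor reliability plus cohort aggregates.

    Cohort medians/IQRs are computed per sensor first, then aggregated —
    never from pooled minutes.
    """

    per_sensor: pd.DataFrame
    gaps: list[GapRecord]
    gap_counts_by_category: dict[str, int]
    gap_minutes_by_cause: dict[int | None, int]
    cause_share_of_gap_minutes: dict[int | None, float]
    cause_share_of_monitoring_minutes: dict[int | None, float]
    device_related_gap_minutes: int
    total_monitoring_minutes: int
    total_gap_minutes: int
    consensus_display_pass: bool
    consensus_device_gap_pass: bool

    def median_iqr(self, column: str) -> tuple[float, float, float]:
        s = self.per_sensor[column]
        return float(s.median()), float(s.quantile(0.25)), float(s.quantile(0.75))

    def summary(self) -> str:
        lines = ["Reliability summary", "==================="]
        for col, label in [
            ("actual_monitoring_minutes", "actual monitoring (min)"),
            ("displayed_minutes", "real-time display (min)"),
            ("pct_display_of_expected", "display / expected 72 h (%)"),
            ("pct_display_of_actual", "display / actual (%)"),
            ("gap_minutes", "data gaps (min)"),
            ("n_calibrations", "calibrations"),
        ]:
            m, lo, hi = self.median_iqr(col)
            lines.append(f"{label:<30} {m:.1f} [{lo:.1f}/{hi:.1f}]")
        lines.append(
            f"gaps: {sum(self.gap_counts_by_category.values())} total "
            + " ".join(f"{k}={v}" for k, v in self.gap_counts_by_category.items())
        )
        lines.append(
            f"consensus display >95%: {'pass' if self.consensus_display_pass else 'FAIL'}; "
            f"device-related gaps <30 min: {'pass' if self.consensus_device_gap_pass else 'FAIL'}"
        )
        return "\n".join(lines)


def cause_shares(
    gap_minutes_by_cause: Mapping[int | None, int], denominator: int
) -> dict[int | None, float]:
    """Percentage share of each gap cause over a minute denominator."""
    if denominator <= 0:
        return {k: 0.0 for k in gap_minutes_by_cause}
    return {k: v / denominator * 100.0 for k, v in gap_minutes_by_cause.items()}


def device_related_share(shares: Mapping[int | None, float]) -> float:
    """Summed share of the device-related causes (codes 1-3)."""
    return float(sum(v for k, v in shares.items() if k in DEVICE_RELATED_CODES))


def reliability_summary(
    sessions: Sequence[SensorSession],
    display_threshold_pct: float = 95.0,
    display_denominator: str = "actual",
) -> ReliabilityReport:
    if not sessions:
        raise ValueError("reliability_summary requires at least one session")
    rows = []
    all_gaps: list[GapRecord] = []
    for s in sessions:
        gaps = detect_gaps(s)
        all_gaps.extend(gaps)
        gap_min = sum(g.duration_min for g in gaps)
        actual = s.monitoring_minutes
        displayed = len(s.samples)
        rows.append(
            SensorReliability(
                sensor_id=s.sensor_id,
                expected_minutes=EXPECTED_MINUTES,
                actual_monitoring_minutes=actual,
                displayed_minutes=displayed,
                gap_minutes=gap_min,
                pct_display_of_expected=displayed / EXPECTED_MINUTES * 100.0,
                pct_display_of_actual=displayed / actual * 100.0 if actual else 0.0,
                n_gaps=len(gaps),
                n_calibrations=len(s.calibrations),
            )
        )
    per_sensor = pd.DataFrame([vars(r) for r in rows]).set_index("sensor_id")

    counts = {c.value: 0 for c in GapCategory}
    minutes_by_cause: dict[int | None, int] = {}
    for g in all_gaps:
        counts[g.category.value] += 1
        minutes_by_cause[g.cause_code] = minutes_by_cause.get(g.cause_code, 0) + g.duration_min
    total_gap = int(per_sensor["gap_minutes"].sum())
    total_mon = int(per_sensor["actual_monitoring_minutes"].sum())
    share_gap = cause_shares(minutes_by_cause, total_gap)
    share_mon = cause_shares(minutes_by_cause, total_mon)
    device_min = sum(g.duration_min for g in all_gaps if g.device_related)

    col = (
        "pct_display_of_actual" if display_denominator == "actual" else "pct_display_of_expected"
    )
    display_pass = bool(per_sensor[col].median() > display_threshold_pct)
    device_gap_pass = all(
        g.duration_min < 30 for g in all_gaps if g.device_related
    )
    return ReliabilityReport(
        per_sensor=per_sensor,
        gaps=all_gaps,
        gap_counts_by_category=counts,
        gap_minutes_by_cause=minutes_by_cause,
        cause_share_of_gap_minutes=share_gap,
        cause_share_of_monitoring_minutes=share_mon,
        device_related_gap_minutes=device_min,
        total_monitoring_minutes=total_mon,
        total_gap_minutes=total_gap,
        consensus_display_pass=display_pass,
        consensus_device_gap_pass=device_gap_pass,
    )


def gaps_to_frame(gaps: Iterable[GapRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sensor_id": g.sensor_id,
                "start": g.start,
                "end": g.end,
                "duration_min": g.duration_min,
                "category": g.category.value,
                "cause_code": g.cause_code,
            }
            for g in gaps
        ]
    )
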