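"""Intra-individual longitudinal and parallel glycemic-control comparisons.

Longitudinal: for patients with reference data covering 72 h both before
the first sensor start and after the last sensor end, glycemic metrics are
computed from the intermittent reference series in three contiguous
windows — 72 h before CGM, the actual monitoring span, and 72 h after —
and compared across windows (Friedman, pairwise Wilcoxon post hoc).

Parallel: for patients whose per-patient MARD is below a threshold
(default 14 %, the consensus accuracy bound), the same metrics are
computed from (a) the intermittent reference series during monitoring —
including draws taken during display gaps — and (b) the full per-minute
CGM series, and compared pairwise (Wilcoxon). Dense CGM sampling is
expected to catch nadirs and excursions the intermittent series misses.

Cohort medians/IQR are always computed per patient first, then aggregated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_model import PatientRecord
from .glycemic_metrics import GlycemicBands, DEFAULT_BANDS, glycemic_summary
from .pairing import PairedReading

#: a window counts as covered if reference data reach within this of its edges
WINDOW_EDGE_TOLERANCE = pd.Timedelta(hours=4)
WINDOW_HOURS = 72
#: below this many paired differences Wilcoxon uses the exact distribution
WILCOXON_EXACT_N = 25

METRICS = [
    "n_readings",
    "n_hypo_events",
    "n_hyper_events",
    "time_in_target_pct",
    "time_below_target_pct",
    "time_above_target_pct",
    "min",
    "max",
    "mean",
    "sd",
    "gli",
]


def _cgm_span(record: PatientRecord) -> tuple[pd.Timestamp, pd.Timestamp]:
    if not record.sessions:
        raise ValueError(f"patient {record.patient_id} has no sessions")
    return (
        min(s.init_time for s in record.sessions),
        max(s.end_time for s in record.sessions),
    )


def _window_series(
    record: PatientRecord, start: pd.Timestamp, end: pd.Timestamp
) -> pd.Series:
    ref = record.reference_series()
    return ref[(ref.index >= start) & (ref.index <= end)]


def _covered(series: pd.Series, start: pd.Timestamp, end: pd.Timestamp) -> bool:
    if len(series) < 2:
        return False
    return (
        series.index[0] - start <= WINDOW_EDGE_TOLERANCE
        and end - series.index[-1] <= WINDOW_EDGE_TOLERANCE
    )


def _summary_row(series: pd.Series, bands: GlycemicBands) -> dict[str, float]:
    s = glycemic_summary(series, bands)
    return {m: s.as_dict()[m] for m in METRICS}


def _wilcoxon(a: np.ndarray, b: np.ndarray) -> float:
    d = a - b
    if np.all(d == 0):
        return 1.0
    method = "exact" if len(d) < WILCOXON_EXACT_N else "approx"
    try:
        return float(stats.wilcoxon(a, b, zero_method="wilcox", method=method).pvalue)
    except ValueError:
        return float("nan")


def median_iqr_table(per_patient: pd.DataFrame) -> pd.DataFrame:
    """Cohort median and quartiles per metric from a patients x metrics frame."""
    return pd.DataFrame(
        {
            "median": per_patient.median(),
            "q1": per_patient.quantile(0.25),
            "q3": per_patient.quantile(0.75),
        }
    )


@dataclass
class LongitudinalResult:
    per_patient: dict[str, pd.DataFrame]   # window -> patients x metrics
    cohort: dict[str, pd.DataFrame]        # window -> metric median/IQR
    friedman_p: dict[str, float]           # metric -> p across the 3 windows
    pairwise_p: dict[str, dict[str, float]]  # metric -> {before_during, ...}
    excluded_patients: list[str]

    def summary(self) -> str:
        lines = ["Longitudinal analysis (reference glucose, per patient)",
                 "======================================================="]
        pats = next(iter(self.per_patient.values())).index if self.per_patient else []
        lines.append(f"patients with full before/during/after coverage: {len(pats)}")
        for m in METRICS:
            row = "  ".join(
                f"{w}: {self.cohort[w].loc[m, 'median']:.1f}"
                f" [{self.cohort[w].loc[m, 'q1']:.1f}/{self.cohort[w].loc[m, 'q3']:.1f}]"
                for w in ("before", "during", "after")
            )
            lines.append(f"{m:<22} {row}  p={self.friedman_p.get(m, float('nan')):.3f}")
        return "\n".join(lines)


def longitudinal_compare(
    records: Mapping[str, PatientRecord],
    bands: GlycemicBands = DEFAULT_BANDS,
    window_hours: int = WINDOW_HOURS,
) -> LongitudinalResult:
    span = pd.Timedelta(hours=window_hours)
    rows: dict[str, dict[str, dict[str, float]]] = {"before": {}, "during": {}, "after": {}}
    excluded: list[str] = []
    for pid in sorted(records):
        rec = records[pid]
        if not rec.sessions:
            excluded.append(pid)
            continue
        start, end = _cgm_span(rec)
        windows = {
            "before": (start - span, start - pd.Timedelta(minutes=1)),
            "during": (start, end),
            "after": (end + pd.Timedelta(minutes=1), end + span),
        }
        series = {w: _window_series(rec, a, b) for w, (a, b) in windows.items()}
        if not all(_covered(series[w], *windows[w]) for w in windows):
            excluded.append(pid)
            continue
        for w in windows:
            rows[w][pid] = _summary_row(series[w], bands)

    per_patient = {w: pd.DataFrame.from_dict(rows[w], orient="index") for w in rows}
    cohort = {w: median_iqr_table(df) for w, df in per_patient.items()}
    friedman_p: dict[str, float] = {}
    pairwise_p: dict[str, dict[str, float]] = {}
    pats = per_patient["before"].index
    if len(pats) >= 3:
        for m in METRICS:
            b = per_patient["before"].loc[pats, m].to_numpy()
            d = per_patient["during"].loc[pats, m].to_numpy()
            a = per_patient["after"].loc[pats, m].to_numpy()
            if np.all(b == d) and np.all(d == a):
                friedman_p[m] = 1.0
            else:
                friedman_p[m] = float(stats.friedmanchisquare(b, d, a).pvalue)
            pairwise_p[m] = {
                "before_during": _wilcoxon(b, d),
                "before_after": _wilcoxon(b, a),
                "during_after": _wilcoxon(d, a),
            }
    return LongitudinalResult(per_patient, cohort, friedman_p, pairwise_p, excluded)


@dataclass
class ParallelResult:
    per_patient: dict[str, pd.DataFrame]   # "intermittent"/"cgm" -> patients x metrics
    cohort: dict[str, pd.DataFrame]
    wilcoxon_p: dict[str, float]
    included_patients: list[str]
    patient_mard: dict[str, float]

    def summary(self) -> str:
        lines = ["Parallel analysis: intermittent reference vs CGM series",
                 "======================================================="]
        lines.append(f"patients below the MARD filter: {len(self.included_patients)}")
        for m in METRICS:
            if not self.included_patients:
                break
            i = self.cohort["intermittent"].loc[m]
            c = self.cohort["cgm"].loc[m]
            lines.append(
                f"{m:<22} BG {i['median']:.1f} [{i['q1']:.1f}/{i['q3']:.1f}]"
                f"  CGM {c['median']:.1f} [{c['q1']:.1f}/{c['q3']:.1f}]"
                f"  p={self.wilcoxon_p.get(m, float('nan')):.3f}"
            )
        return "\n".join(lines)


def parallel_compare(
    records: Mapping[str, PatientRecord],
    pairs: Sequence[PairedReading],
    mard_threshold: float = 14.0,
    bands: GlycemicBands = DEFAULT_BANDS,
) -> ParallelResult:
    """Compare intermittent-vs-continuous metrics in accurately-monitored patients.

    With the threshold at infinity every patient with pairs qualifies;
    tightening it can only shrink the cohort. An empty qualifying set is a
    valid (empty) result, not an error.
    """
    by_patient: dict[str, list[float]] = {}
    for p in pairs:
        by_patient.setdefault(p.patient_id, []).append(p.ard)
    patient_mard = {pid: float(np.mean(a)) for pid, a in by_patient.items()}
    included = [
        pid
        for pid in sorted(records)
        if pid in patient_mard and patient_mard[pid] < mard_threshold
    ]
    rows: dict[str, dict[str, dict[str, float]]] = {"intermittent": {}, "cgm": {}}
    kept: list[str] = []
    for pid in included:
        rec = records[pid]
        start, end = _cgm_span(rec)
        ref = _window_series(rec, start, end)
        cgm_parts = [s.to_series() for s in rec.sessions]
        cgm = pd.concat(cgm_parts).sort_index()
        if len(ref) < 2 or len(cgm) < 2:
            continue
        kept.append(pid)
        rows["intermittent"][pid] = _summary_row(ref, bands)
        rows["cgm"][pid] = _summary_row(cgm, bands)
    per_patient = {k: pd.DataFrame.from_dict(v, orient="index") for k, v in rows.items()}
    cohort = {k: median_iqr_table(df) for k, df in per_patient.items()}
    wilcoxon_p: dict[str, float] = {}
    if len(kept) >= 2:
        for m in METRICS:
            a = per_patient["intermittent"].loc[kept, m].to_numpy(dtype=float)
            b = per_patient["cgm"].loc[kept, m].to_numpy(dtype=float)
            wilcoxon_p[m] = _wilcoxon(a, b)
    return ParallelResult(per_patient, cohort, wilcoxon_p, kept, patient_mard)
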