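"""Stratified accuracy, covariate correlations and the time-shift lag scan.

Accuracy is stratified by reference glucose range (< 80, 80-179,
> 179 mg/dl) and by each patient's daily glycemic variability (pairs drawn
within one SD of the day's mean reference glucose vs beyond it). Clinical
covariates are correlated with per-pair ARD (Spearman for continuous
covariates, rank-sum comparison for binary flags). The lag scan recomputes
MARD after pairing each reference with the sensor value a fixed number of
minutes later (1-30 min, the sensor trailing blood), so a diffusion or
processing delay shows up as an interior minimum of MARD over the shift.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_model import PatientRecord
from .pairing import (
    DEFAULT_PAIRING_WINDOW_MIN,
    PairedReading,
    ard,
    extract_pairs,
)

GLUCOSE_RANGE_EDGES = (80.0, 180.0)  # <80, 80-179, >179 mg/dl
COVARIATE_MATCH_TOLERANCE = pd.Timedelta(hours=4)


@dataclass
class StratifiedMard:
    stratum: str
    n_pairs: int
    mard_median: float | None
    iqr: tuple[float, float] | None

    @staticmethod
    def from_ards(stratum: str, ards: np.ndarray) -> "StratifiedMard":
        if len(ards) == 0:
            return StratifiedMard(stratum, 0, None, None)
        return StratifiedMard(
            stratum,
            len(ards),
            float(np.median(ards)),
            (float(np.percentile(ards, 25)), float(np.percentile(ards, 75))),
        )


@dataclass
class StratifiedResult:
    strata: list[StratifiedMard]
    statistic: float | None
    p_value: float | None
    test: str
    n_unassigned: int = 0


def mard_by_glucose_range(
    pairs: Sequence[PairedReading], edges: tuple[float, float] = GLUCOSE_RANGE_EDGES
) -> StratifiedResult:
    """Per-stratum ARD median/IQR by reference range, Kruskal-Wallis across strata."""
    lo, hi = edges
    labels = [f"<{lo:g}", f"{lo:g}-{hi - 1:g}", f">{hi - 1:g}"]
    groups: dict[str, list[float]] = {lab: [] for lab in labels}
    for p in pairs:
        if p.reference_value < lo:
            groups[labels[0]].append(p.ard)
        elif p.reference_value < hi:
            groups[labels[1]].append(p.ard)
        else:
            groups[labels[2]].append(p.ard)
    strata = [StratifiedMard.from_ards(lab, np.array(groups[lab])) for lab in labels]
    non_empty = [np.array(groups[lab]) for lab in labels if groups[lab]]
    stat = p_val = None
    if len(non_empty) >= 2:
        stat, p_val = stats.kruskal(*non_empty)
        stat, p_val = float(stat), float(p_val)
    return StratifiedResult(strata, stat, p_val, "kruskal-wallis")


def _daily_reference_stats(
    record: PatientRecord, window_hours: float = 24.0
) -> pd.DataFrame:
    """Per 24-h block (anchored on first monitoring minute): mean and SD of reference."""
    if not record.sessions:
        raise ValueError("record has no sensor sessions")
    anchor = min(s.init_time for s in record.sessions)
    ref = record.reference_series()
    day = ((ref.index - anchor) / pd.Timedelta(hours=window_hours)).astype(int)
    g = ref.groupby(day)
    return pd.DataFrame({"mean": g.mean(), "sd": g.std(ddof=1), "n": g.size()})


def mard_by_variability_stratum(
    records: Mapping[str, PatientRecord],
    pairs: Sequence[PairedReading],
) -> StratifiedResult:
    """Pairs within 1 SD of that day's mean reference glucose vs beyond 1 SD.

    Days with fewer than two reference values give no SD; their pairs are
    counted as unassigned. Strata compared with a Mann-Whitney U test.
    """
    within, beyond = [], []
    n_unassigned = 0
    daily = {pid: _daily_reference_stats(rec) for pid, rec in records.items() if rec.sessions}
    anchors = {
        pid: min(s.init_time for s in rec.sessions)
        for pid, rec in records.items()
        if rec.sessions
    }
    for p in pairs:
        if p.patient_id not in daily:
            n_unassigned += 1
            continue
        day = int((p.timestamp - anchors[p.patient_id]) / pd.Timedelta(hours=24))
        stats_day = daily[p.patient_id]
        if day not in stats_day.index or stats_day.loc[day, "n"] < 2:
            n_unassigned += 1
            continue
        mu, sd = stats_day.loc[day, "mean"], stats_day.loc[day, "sd"]
        if sd == 0 or abs(p.reference_value - mu) <= sd:
            within.append(p.ard)
        else:
            beyond.append(p.ard)
    strata = [
        StratifiedMard.from_ards("within_1sd", np.array(within)),
        StratifiedMard.from_ards("beyond_1sd", np.array(beyond)),
    ]
    stat = p_val = None
    if within and beyond:
        stat, p_val = stats.mannwhitneyu(within, beyond, alternative="two-sided")
        stat, p_val = float(stat), float(p_val)
    return StratifiedResult(strata, stat, p_val, "mann-whitney", n_unassigned)


@dataclass
class CovariateAssociation:
    name: str
    kind: str                 # "spearman" or "rank-sum"
    n: int
    statistic: float | None   # rho, or the U statistic
    p_value: float | None
    r_squared: float | None   # rho^2 for continuous covariates


def covariate_correlations(
    records: Mapping[str, PatientRecord],
    pairs: Sequence[PairedReading],
    tolerance: pd.Timedelta = COVARIATE_MATCH_TOLERANCE,
) -> list[CovariateAssociation]:
    """Associate per-pair ARD with each covariate found on the records.

    Each pair is matched to the nearest covariate value within the
    tolerance (default 4 h, blood-gas cadence). Covariates taking only the
    values 0/1 are treated as group flags (diabetes, SIRS, vasopressors)
    and compared with a rank-sum test; all others via Spearman correlation.
    Absent covariates are simply skipped.
    """
    names: set[str] = set()
    for rec in records.values():
        if rec.covariates is not None:
            names.update(rec.covariates["name"].unique())
    out: list[CovariateAssociation] = []
    for name in sorted(names):
        ards, values = [], []
        for p in pairs:
            rec = records.get(p.patient_id)
            if rec is None or rec.covariates is None:
                continue
            sub = rec.covariates[rec.covariates["name"] == name]
            if sub.empty:
                continue
            deltas = (sub["timestamp"] - p.timestamp).abs()
            i = deltas.idxmin()
            if deltas[i] <= tolerance:
                ards.append(p.ard)
                values.append(float(sub.loc[i, "value"]))
        n = len(ards)
        if n < 3:
            out.append(CovariateAssociation(name, "skipped", n, None, None, None))
            continue
        vals = np.array(values)
        if set(np.unique(vals)) <= {0.0, 1.0}:
            a = [x for x, v in zip(ards, vals) if v == 1.0]
            b = [x for x, v in zip(ards, vals) if v == 0.0]
            if not a or not b:
                out.append(CovariateAssociation(name, "skipped", n, None, None, None))
                continue
            u, p_val = stats.mannwhitneyu(a, b, alternative="two-sided")
            out.append(CovariateAssociation(name, "rank-sum", n, float(u), float(p_val), None))
        else:
            if np.all(vals == vals[0]):
                out.append(CovariateAssociation(name, "skipped", n, None, None, None))
                continue
            rho, p_val = stats.spearmanr(ards, vals)
            out.append(
                CovariateAssociation(name, "spearman", n, float(rho), float(p_val), float(rho) ** 2)
            )
    return out


@dataclass
class LagProfile:
    """MARD as a function of the sensor-after-reference pairing shift."""

    shifts: list[int]
    mard_at_shift: list[float]
    n_at_shift: list[int]

    @property
    def argmin_shift(self) -> int:
        return self.shifts[int(np.argmin(self.mard_at_shift))]


def time_shift_mard(
    record: PatientRecord,
    shifts: Iterable[int] = range(0, 31),
    window_min: int = DEFAULT_PAIRING_WINDOW_MIN,
) -> LagProfile:
    """Recompute MARD pairing each reference with the sensor ``k`` min later.

    Eligibility (calibration exclusions) is fixed at shift 0, so the same
    references are rescanned at every shift; a reference with no sensor
    value in the window at ``t + k`` drops out for that shift only. Shift 0
    reproduces the baseline pairing exactly. Negative shifts (sensor
    earlier than blood) are allowed.
    """
    base = extract_pairs(record, window_min).pairs
    ref_points = [(p.timestamp, p.reference_value) for p in base]
    sessions = [(s.sample_times(), s) for s in record.sessions]
    window = pd.Timedelta(minutes=window_min)
    out_shifts, out_mard, out_n = [], [], []
    for k in shifts:
        delta = pd.Timedelta(minutes=int(k))
        ards = []
        for t_ref, v_ref in ref_points:
            t = t_ref + delta
            best = None
            for times, session in sessions:
                if not (session.init_time <= t <= session.end_time):
                    continue
                idx = times.searchsorted(t, side="right") - 1
                if idx < 0 or t - times[idx] > window:
                    continue
                if best is None or times[idx] > best[0]:
                    best = (times[idx], session.samples[idx].value)
            if best is not None:
                ards.append(ard(v_ref, best[1]))
        if ards:
            out_shifts.append(int(k))
            out_mard.append(float(np.mean(ards)))
            out_n.append(len(ards))
    if not out_shifts:
        raise ValueError("no shift produced any pair; trace too sparse")
    return LagProfile(out_shifts, out_mard, out_n)


def cohort_lag_argmins(
    records: Mapping[str, PatientRecord],
    shifts: Iterable[int] = range(0, 31),
    window_min: int = DEFAULT_PAIRING_WINDOW_MIN,
) -> dict[str, int]:
    """Per-patient argmin shift of the lag profile (patients without pairs skipped)."""
    out = {}
    for pid in sorted(records):
        try:
            out[pid] = time_shift_mard(records[pid], shifts, window_min).argmin_shift
        except ValueError:
            continue
    return out
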