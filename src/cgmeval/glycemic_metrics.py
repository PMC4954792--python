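"""Dysglycemia bands, event counting, time in range and variability.

Bands (mg/dl, inclusive integer bounds as printed in clinical tables):
severe hypoglycemia <= 40, moderate hypoglycemia 41-70, euglycemia 71-149,
moderate hyperglycemia 150-179, severe hyperglycemia > 179. The insulin
target used for therapy (80-149) is carried as a separate labelled range
and never mixed with the 71-149 analysis bands.

Variability is summarised by the sample SD and the glycemic lability index
(GLI): the sum of squared consecutive glucose changes divided by the
elapsed hours between them, accumulated per 24-h window (1440 min) and
averaged across windows; partial windows are scaled up to 24 h.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd


class Band(str, enum.Enum):
    SEVERE_HYPO = "severe_hypo"
    MODERATE_HYPO = "moderate_hypo"
    EUGLYCEMIA = "euglycemia"
    MODERATE_HYPER = "moderate_hyper"
    SEVERE_HYPER = "severe_hyper"


@dataclass(frozen=True)
class GlycemicBands:
    """Band cut-points (inclusive upper bounds) and the insulin target range."""

    severe_hypo_max: float = 40.0
    moderate_hypo_max: float = 70.0
    euglycemia_max: float = 149.0
    moderate_hyper_max: float = 179.0
    insulin_target: tuple[float, float] = (80.0, 149.0)

    def __post_init__(self) -> None:
        cuts = (self.severe_hypo_max, self.moderate_hypo_max,
                self.euglycemia_max, self.moderate_hyper_max)
        if not all(a < b for a, b in zip(cuts, cuts[1:])):
            raise ValueError("band cut-points must be strictly increasing")

    @property
    def target(self) -> tuple[float, float]:
        """The 71-149 analysis target range (lower edge of euglycemia, its max)."""
        return (self.moderate_hypo_max + 1, self.euglycemia_max)


DEFAULT_BANDS = GlycemicBands()


def classify_band(value: float, bands: GlycemicBands = DEFAULT_BANDS) -> Band:
    if value <= 0:
        raise ValueError("glucose value must be positive")
    if value <= bands.severe_hypo_max:
        return Band.SEVERE_HYPO
    if value <= bands.moderate_hypo_max:
        return Band.MODERATE_HYPO
    if value <= bands.euglycemia_max:
        return Band.EUGLYCEMIA
    if value <= bands.moderate_hyper_max:
        return Band.MODERATE_HYPER
    return Band.SEVERE_HYPER


def count_events(values: Sequence[float], band_predicate: Callable[[float], bool]) -> int:
    """Count newly developed events: entries into the band from outside.

    A series that starts inside the band contributes one event; re-entries
    after leaving the band each count again.
    """
    events = 0
    inside = False
    for v in values:
        now = bool(band_predicate(v))
        if now and not inside:
            events += 1
        inside = now
    return events


def _segment_time_in(v0: float, v1: float, dt: float, lo: float, hi: float) -> float:
    """Time a linear segment spends with value in [lo, hi]."""
    if v0 == v1:
        return dt if lo <= v0 <= hi else 0.0
    vmin, vmax = min(v0, v1), max(v0, v1)
    overlap = min(vmax, hi) - max(vmin, lo)
    if overlap <= 0:
        return 0.0
    return overlap / (vmax - vmin) * dt


def time_in_ranges(
    series: pd.Series,
    bands: GlycemicBands = DEFAULT_BANDS,
    method: str = "interpolated",
) -> dict[str, float]:
    """Percentage of time below / in / above the 71-149 target range.

    ``interpolated`` (default) joins consecutive samples piecewise-linearly
    and measures time exactly, including edge-crossing times — appropriate
    for intermittent reference series. ``readings`` returns the plain share
    of readings per range (the discrete alternative for sparse series).
    Edge values sit inside the target (the printed bands are inclusive).
    """
    if len(series) < 2 and method == "interpolated":
        raise ValueError("time_in_ranges needs at least two samples to interpolate")
    lo, hi = bands.target
    values = series.to_numpy(dtype=float)
    if method == "readings":
        n = len(values)
        below = float(np.sum(values < lo)) / n * 100.0
        above = float(np.sum(values > hi)) / n * 100.0
        return {"below": below, "target": 100.0 - below - above, "above": above}
    if method != "interpolated":
        raise ValueError(f"unknown method {method!r}")
    times = series.index.view("int64") / 60e9  # minutes
    total = times[-1] - times[0]
    if total <= 0:
        raise ValueError("series must span positive time")
    t_below = t_target = 0.0
    for i in range(len(values) - 1):
        dt = times[i + 1] - times[i]
        v0, v1 = values[i], values[i + 1]
        t_below += _segment_time_in(v0, v1, dt, 0.0, np.nextafter(lo, -np.inf))
        t_target += _segment_time_in(v0, v1, dt, lo, hi)
    below = t_below / total * 100.0
    target = t_target / total * 100.0
    return {"below": below, "target": target, "above": 100.0 - below - target}


def gli_contributions(series: pd.Series) -> np.ndarray:
    """Per-step GLI contributions (delta g)^2 / delta t(h) between samples."""
    values = series.to_numpy(dtype=float)
    hours = series.index.view("int64") / 3.6e12
    dg = np.diff(values)
    dt = np.diff(hours)
    if np.any(dt <= 0):
        raise ValueError("series timestamps must be strictly increasing")
    return dg**2 / dt


def variability(series: pd.Series, window_hours: float = 24.0) -> tuple[float, float]:
    """Sample SD (mg/dl) and GLI ((mg/dl)^2/h per window, default 24 h).

    GLI contributions are assigned to the window containing the step's start
    time; each window's total is rescaled to the full window length (partial
    trailing windows would otherwise be under-weighted), then averaged.
    """
    if len(series) < 2:
        raise ValueError("variability needs at least two samples")
    sd = float(series.to_numpy(dtype=float).std(ddof=1))
    hours = series.index.view("int64") / 3.6e12
    start, end = hours[0], hours[-1]
    contrib = gli_contributions(series)
    n_windows = max(1, int(np.ceil((end - start) / window_hours - 1e-12)))
    totals = np.zeros(n_windows)
    widx = np.minimum(((hours[:-1] - start) / window_hours).astype(int), n_windows - 1)
    np.add.at(totals, widx, contrib)
    scales = np.ones(n_windows)
    for w in range(n_windows):
        covered = min(end, start + (w + 1) * window_hours) - (start + w * window_hours)
        if 0 < covered < window_hours:
            scales[w] = window_hours / covered
    gli = float(np.mean(totals * scales))
    return sd, gli


@dataclass
class GlycemicSummary:
    """Per-series glycemic-control metrics (one patient, one data source)."""

    n_readings: int
    mean: float
    sd: float
    gli: float
    time_in_target_pct: float
    time_below_target_pct: float
    time_above_target_pct: float
    min: float
    max: float
    n_hypo_events: int          # newly developed events below the target floor
    n_hyper_events: int         # newly developed events above the target ceiling
    events_by_band: dict[str, int] = field(default_factory=dict)

    def as_dict(self) -> dict[str, float]:
        d = {
            "n_readings": self.n_readings,
            "mean": self.mean,
            "sd": self.sd,
            "gli": self.gli,
            "time_in_target_pct": self.time_in_target_pct,
            "time_below_target_pct": self.time_below_target_pct,
            "time_above_target_pct": self.time_above_target_pct,
            "min": self.min,
            "max": self.max,
            "n_hypo_events": self.n_hypo_events,
            "n_hyper_events": self.n_hyper_events,
        }
        return d


def glycemic_summary(
    series: pd.Series,
    bands: GlycemicBands = DEFAULT_BANDS,
    time_method: str = "interpolated",
) -> GlycemicSummary:
    """All glycemic metrics for one time-ordered glucose series."""
    values = series.to_numpy(dtype=float)
    if len(values) < 2:
        raise ValueError("glycemic_summary needs at least two samples")
    sd, gli = variability(series)
    shares = time_in_ranges(series, bands, method=time_method)
    lo, hi = bands.target
    per_band = {
        Band.SEVERE_HYPO.value: count_events(values, lambda v: v <= bands.severe_hypo_max),
        Band.MODERATE_HYPO.value: count_events(
            values, lambda v: bands.severe_hypo_max < v <= bands.moderate_hypo_max
        ),
        Band.EUGLYCEMIA.value: count_events(values, lambda v: lo <= v <= bands.euglycemia_max),
        Band.MODERATE_HYPER.value: count_events(
            values, lambda v: bands.euglycemia_max < v <= bands.moderate_hyper_max
        ),
        Band.SEVERE_HYPER.value: count_events(values, lambda v: v > bands.moderate_hyper_max),
    }
    return GlycemicSummary(
        n_readings=len(values),
        mean=float(values.mean()),
        sd=sd,
        gli=gli,
        time_in_target_pct=shares["target"],
        time_below_target_pct=shares["below"],
        time_above_target_pct=shares["above"],
        min=float(values.min()),
        max=float(values.max()),
        n_hypo_events=count_events(values, lambda v: v < lo),
        n_hyper_events=count_events(values, lambda v: v > hi),
        events_by_band=per_band,
    )
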