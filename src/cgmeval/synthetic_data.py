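"""Synthetic ICU-CGM cohort generator.

No patient-level data accompany published ICU CGM evaluations, so every
pipeline stage here is exercised on synthetic cohorts with the statistical
structure the analysis assumes:

* latent blood glucose per patient: a mean-reverting Ornstein-Uhlenbeck
  process on a 1-minute grid (stationary mean ~134 mg/dl, SD ~25 mg/dl,
  relaxation time 2 h), optionally with superimposed dysglycemic episodes;
* interstitial glucose: a first-order diffusion lag (time constant tau,
  default 10 min) applied to the blood path;
* the sensor: a multiplicative gain that re-anchors to the reference at
  every calibration and random-walks between calibrations (drift), plus
  additive Gaussian noise — so calibrating during a steep excursion bakes
  in error, reproducible as a test scenario;
* display gaps carved by a Poisson process with the four-category duration
  mixture and annotated causes; premature removals; a second sensor when
  the first fails early, mirroring study practice;
* intermittent reference draws every 2-4 h (arterial/venous) over the
  whole stay, the start/+1 h/+2 h then 8-hourly calibration schedule with
  recalibration after gaps > 15 min, and autocorrelated clinical
  covariates.

Default parameter values are calibration targets taken from the evaluated
trial's published tables, not claims of physiological fidelity. All output
is a pure function of the config including its seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .io_model import (
    CalibrationEvent,
    GlucoseSample,
    PatientRecord,
    SensorSession,
    Source,
    write_dataset,
)

MINUTE = pd.Timedelta(minutes=1)
EPOCH = pd.Timestamp("2024-03-01 08:00")


@dataclass(frozen=True)
class SimulationConfig:
    """All generative parameters. The seed fully determines the output."""

    n_patients: int = 20
    seed: int = 0
    # blood-glucose dynamics
    bg_mean: float = 134.0            # cohort set-point, mg/dl
    bg_between_sd: float = 10.0       # between-patient SD of the set-point
    bg_sd: float = 25.0               # stationary within-patient SD, mg/dl
    mean_reversion_hours: float = 2.0
    dysglycemia_pressure: float = 0.0  # episode rate per h (0 = off)
    # sensor physics
    lag_min: float = 10.0             # interstitial diffusion time constant
    sensor_noise_sd: float = 8.0      # additive noise, mg/dl
    drift_sd_per_h: float = 0.01      # gain random-walk SD per hour
    #: "reference": calibration re-anchors the gain to the blood reference,
    #: so calibrating while blood and interstitial diverge bakes in error;
    #: "exact": idealized calibration resets the gain to 1 (sensor tracks
    #: interstitial exactly when noise and drift are off)
    calibration_mode: str = "reference"
    # sampling schedules
    ref_interval_h: tuple[float, float] = (2.0, 4.0)
    calibration_interval_h: float = 8.0
    # gaps (rate 155 gaps / 1337.1 h of monitoring)
    gap_rate_per_h: float = 0.116
    gap_category_probs: tuple[float, float, float, float] = (0.439, 0.226, 0.174, 0.161)
    gap_duration_ranges: tuple[tuple[int, int], ...] = ((1, 14), (15, 30), (31, 120), (121, 540))
    gap_cause_weights: tuple[float, ...] = (23.3, 15.0, 10.9, 15.6, 3.4, 27.8, 4.0)
    # removals (21 of 31 sensors premature)
    premature_removal_prob: float = 0.677
    premature_removal_range_h: tuple[float, float] = (4.0, 70.0)
    removal_cause_weights: tuple[float, ...] = (7, 7, 1, 1, 1, 2, 2)
    second_sensor_if_short: bool = True   # restart when < 48 h achieved
    # cohort composition
    long_stay_fraction: float = 0.5   # patients with 72 h of data either side
    arterial_fraction: float = 0.893
    with_covariates: bool = True
    confounder_coupling: float = 0.0  # scales sensor noise with SOFA when > 0

    def __post_init__(self) -> None:
        if self.bg_mean <= 0:
            raise ValueError("bg_mean must be positive")
        for name in ("bg_sd", "sensor_noise_sd", "drift_sd_per_h", "gap_rate_per_h",
                     "dysglycemia_pressure"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.lag_min < 0:
            raise ValueError("lag_min must be >= 0")
        if abs(sum(self.gap_category_probs) - 1.0) > 1e-9:
            raise ValueError("gap_category_probs must sum to 1")
        if self.calibration_mode not in ("reference", "exact"):
            raise ValueError("calibration_mode must be 'reference' or 'exact'")

    def replace(self, **kw) -> "SimulationConfig":
        return dataclasses.replace(self, **kw)


def noiseless_config(n_patients: int = 20, seed: int = 0, **kw) -> SimulationConfig:
    """A noise-free, lag-free, gap-free cohort: sensor == interstitial == blood."""
    base = dict(
        n_patients=n_patients,
        seed=seed,
        lag_min=0.0,
        sensor_noise_sd=0.0,
        drift_sd_per_h=0.0,
        gap_rate_per_h=0.0,
        premature_removal_prob=0.0,
        second_sensor_if_short=False,
    )
    base.update(kw)
    return SimulationConfig(**base)


# ---------------------------------------------------------------------------
# dynamics
# ---------------------------------------------------------------------------

def simulate_blood_glucose(
    config: SimulationConfig,
    rng: np.random.Generator,
    n_minutes: int,
    mu: float | None = None,
) -> np.ndarray:
    """Ornstein-Uhlenbeck latent blood-glucose path on the 1-min grid.

    Exact discretization: x_{t+1} = mu + (x_t - mu) phi + s sqrt(1 - phi^2) e_t
    with phi = exp(-1 / T) and T the relaxation time in minutes, so the
    stationary SD equals ``bg_sd`` for any T. Optional dysglycemic episodes
    add transient set-point excursions. Values are floored at 25 mg/dl.
    """
    if mu is None:
        mu = config.bg_mean
    if mu <= 0:
        raise ValueError("set-point must be positive")
    t_min = config.mean_reversion_hours * 60.0
    phi = np.exp(-1.0 / t_min)
    s = config.bg_sd
    path = np.empty(n_minutes)
    baseline = np.full(n_minutes, float(mu))
    if config.dysglycemia_pressure > 0:
        n_ep = rng.poisson(config.dysglycemia_pressure * n_minutes / 60.0)
        for _ in range(n_ep):
            start = int(rng.integers(0, n_minutes))
            length = int(rng.uniform(60, 240))
            amp = rng.normal(60.0, 20.0) * (1 if rng.random() < 0.7 else -1)
            baseline[start : start + length] += amp
    x = rng.normal(0.0, s) if s > 0 else 0.0
    innov = rng.normal(0.0, 1.0, size=n_minutes) * s * np.sqrt(1.0 - phi**2)
    for t in range(n_minutes):
        path[t] = baseline[t] + x
        x = x * phi + innov[t]
    return np.maximum(path, 25.0)


def simulate_interstitial(blood_path: np.ndarray, tau_min: float) -> np.ndarray:
    """First-order diffusion lag dI/dt = (G - I)/tau on the 1-min grid.

    Exact exponential update with the blood value held over each minute;
    tau = 0 returns the blood path. A step input reaches 63.2 % of the step
    after tau minutes.
    """
    if tau_min < 0:
        raise ValueError("tau must be >= 0")
    if tau_min == 0:
        return blood_path.copy()
    a = np.exp(-1.0 / tau_min)
    out = np.empty_like(blood_path)
    out[0] = blood_path[0]
    for t in range(1, len(blood_path)):
        out[t] = blood_path[t] + (out[t - 1] - blood_path[t]) * a
    return out


# ---------------------------------------------------------------------------
# sensor sessions
# ---------------------------------------------------------------------------

@dataclass
class TrueGap:
    start_min: int      # first missing minute, relative to session init
    duration_min: int
    cause_code: int


@dataclass
class SimulatedSensor:
    session: SensorSession
    true_gaps: list[TrueGap]
    premature: bool


def _draw_removal(config: SimulationConfig, rng: np.random.Generator) -> tuple[int, int | None]:
    if rng.random() < config.premature_removal_prob:
        lo, hi = config.premature_removal_range_h
        minutes = int(rng.uniform(lo * 60, hi * 60))
        w = np.array(config.removal_cause_weights, dtype=float)
        cause = int(rng.choice(np.arange(1, 8), p=w / w.sum()))
        return minutes, cause
    return 72 * 60, None


def _carve_gaps(
    config: SimulationConfig, rng: np.random.Generator, n_minutes: int
) -> tuple[np.ndarray, dict[int, int]]:
    """Boolean missing-minute mask plus cause code per gap-start minute."""
    missing = np.zeros(n_minutes, dtype=bool)
    n_gaps = rng.poisson(config.gap_rate_per_h * n_minutes / 60.0)
    causes: dict[int, int] = {}
    cause_w = np.array(config.gap_cause_weights, dtype=float)
    cause_w /= cause_w.sum()
    cat_p = np.array(config.gap_category_probs)
    for _ in range(n_gaps):
        cat = int(rng.choice(4, p=cat_p))
        lo, hi = config.gap_duration_ranges[cat]
        dur = int(rng.integers(lo, hi + 1))
        if n_minutes <= dur + 20:
            continue
        start = int(rng.integers(10, n_minutes - dur - 2))
        missing[start : start + dur] = True
        causes[start] = int(rng.choice(np.arange(1, 8), p=cause_w))
    # keep the first three minutes and the final minute displayed: the
    # start-up calibration needs display, and a trailing gap is a removal
    missing[:3] = False
    missing[n_minutes - 1] = False
    return missing, causes


def _mask_runs(missing: np.ndarray) -> list[tuple[int, int]]:
    """(start, duration) of each contiguous run of True."""
    runs = []
    padded = np.diff(np.concatenate([[0], missing.astype(int), [0]]))
    starts = np.nonzero(padded == 1)[0]
    ends = np.nonzero(padded == -1)[0]
    for s, e in zip(starts, ends):
        runs.append((int(s), int(e - s)))
    return runs


def simulate_sensor(
    config: SimulationConfig,
    rng: np.random.Generator,
    interstitial: np.ndarray,
    blood: np.ndarray,
    init_offset_min: int,
    patient_id: str,
    sensor_id: str,
    start_time: pd.Timestamp,
    noise_scale: np.ndarray | None = None,
) -> SimulatedSensor:
    """One sensor session over interstitial[init_offset : init_offset + removal].

    The multiplicative gain is reset at every calibration so that
    gain x interstitial matches the blood reference at that minute, and
    random-walks between calibrations; Gaussian noise is added on top.
    """
    removal_min, removal_cause = _draw_removal(config, rng)
    removal_min = min(removal_min, len(interstitial) - init_offset_min - 1)
    n = removal_min
    seg_i = interstitial[init_offset_min : init_offset_min + n]
    seg_b = blood[init_offset_min : init_offset_min + n]

    missing, cause_by_start = _carve_gaps(config, rng, n)
    runs = _mask_runs(missing)

    # calibration schedule: 0, +1 h, +2 h, then 8-hourly; plus after gaps > 15 min
    cal_minutes = [0, 60, 120]
    t = 120 + int(config.calibration_interval_h * 60)
    while t < n:
        cal_minutes.append(t)
        t += int(config.calibration_interval_h * 60)
    for start, dur in runs:
        if dur > 15 and start + dur < n:
            cal_minutes.append(start + dur)
    # calibration requires display: shift to the next displayed minute
    displayed = ~missing
    shifted = []
    for m in cal_minutes:
        while m < n and not displayed[m]:
            m += 1
        if m < n:
            shifted.append(m)
    cal_minutes = sorted(set(shifted))

    gain = np.ones(n)
    drift_step = config.drift_sd_per_h / np.sqrt(60.0)
    g = 1.0
    boundaries = cal_minutes + [n]
    for i, m in enumerate(cal_minutes):
        g = seg_b[m] / seg_i[m] if config.calibration_mode == "reference" else 1.0
        stop = boundaries[i + 1]
        length = stop - m
        if drift_step > 0:
            walk = np.concatenate([[0.0], np.cumsum(rng.normal(0.0, drift_step, length - 1))])
        else:
            walk = np.zeros(length)
        gain[m:stop] = g + walk
    noise = rng.normal(0.0, config.sensor_noise_sd, n) if config.sensor_noise_sd > 0 else np.zeros(n)
    if noise_scale is not None:
        noise = noise * noise_scale[init_offset_min : init_offset_min + n]
    values = np.maximum(gain * seg_i + noise, 20.0)

    samples = [
        GlucoseSample(start_time + int(m) * MINUTE, float(values[m]), Source.SENSOR, patient_id)
        for m in np.nonzero(displayed)[0]
    ]
    calibrations = [
        CalibrationEvent(start_time + m * MINUTE, float(seg_b[m])) for m in cal_minutes
    ]
    gap_causes = {}
    true_gaps = []
    for start, dur in runs:
        # annotated cause: the cause of the carve that began the run, else
        # the nearest carve start inside the run (overlap merge)
        code = cause_by_start.get(start)
        if code is None:
            inside = [c for s0, c in cause_by_start.items() if start <= s0 < start + dur]
            code = inside[0] if inside else 7
        gap_causes[start_time + start * MINUTE] = code
        true_gaps.append(TrueGap(start, dur, code))
    session = SensorSession(
        sensor_id=sensor_id,
        patient_id=patient_id,
        init_time=start_time,
        samples=samples,
        calibrations=calibrations,
        removal_time=start_time + (n - 1) * MINUTE,
        removal_cause=removal_cause,
        gap_causes=gap_causes,
    )
    return SimulatedSensor(session, true_gaps, removal_cause is not None)


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------

@dataclass
class SimulatedTruth:
    patient_id: str
    blood: pd.Series          # latent path, 1-min grid
    interstitial: pd.Series
    tau_min: float
    true_gaps: dict[str, list[TrueGap]]
    premature: dict[str, bool]
    long_stay: bool


@dataclass
class SyntheticCohort:
    config: SimulationConfig
    records: dict[str, PatientRecord]
    truth: dict[str, SimulatedTruth]

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Emit the CSV dialect plus a truth bundle (separate CSV set)."""
        out = Path(out_dir)
        paths = write_dataset(self.records, out)
        truth_dir = out / "truth"
        truth_dir.mkdir(parents=True, exist_ok=True)
        gap_rows, path_rows = [], []
        for pid in sorted(self.truth):
            t = self.truth[pid]
            for sid, gaps in t.true_gaps.items():
                for g in gaps:
                    gap_rows.append((pid, sid, g.start_min, g.duration_min, g.cause_code))
            path_rows.append((pid, t.tau_min, t.long_stay))
        pd.DataFrame(
            gap_rows, columns=["patient_id", "sensor_id", "start_min", "duration_min", "cause_code"]
        ).to_csv(truth_dir / "gaps.csv", index=False)
        pd.DataFrame(path_rows, columns=["patient_id", "tau_min", "long_stay"]).to_csv(
            truth_dir / "patients.csv", index=False
        )
        paths["truth_gaps"] = truth_dir / "gaps.csv"
        return paths


def _simulate_covariates(
    rng: np.random.Generator,
    patient_id: str,
    start: pd.Timestamp,
    n_minutes: int,
) -> pd.DataFrame:
    """Autocorrelated clinical covariates at blood-gas cadence (6-hourly)."""
    specs = {  # name: (mean, sd, AR step sd)
        "pO2": (90.0, 15.0, 6.0),
        "temperature": (37.2, 0.7, 0.2),
        "hemoglobin": (9.5, 1.3, 0.2),
        "potassium": (4.2, 0.4, 0.15),
        "lactate": (1.8, 0.8, 0.3),
        "pH": (7.38, 0.05, 0.01),
    }
    times = np.arange(0, n_minutes, 360)
    rows = []
    for name, (mu, sd, step) in specs.items():
        x = rng.normal(mu, sd)
        for t in times:
            rows.append((patient_id, start + int(t) * MINUTE, name, round(float(x), 3)))
            x += rng.normal(0.0, step)
    sofa = int(rng.integers(2, 14))
    for t in np.arange(0, n_minutes, 1440):
        rows.append((patient_id, start + int(t) * MINUTE, "SOFA", float(sofa)))
        sofa = int(np.clip(sofa + rng.integers(-2, 3), 0, 20))
    for name, p in (("diabetes", 0.25), ("SIRS", 1.0), ("vasopressors", 0.35)):
        rows.append((patient_id, start, name, float(rng.random() < p)))
    return pd.DataFrame(rows, columns=["patient_id", "timestamp", "name", "value"])


def generate_patient(
    config: SimulationConfig, patient_seed: np.random.SeedSequence, index: int
) -> tuple[PatientRecord, SimulatedTruth]:
    rng = np.random.default_rng(patient_seed)
    pid = f"P{index + 1:02d}"
    long_stay = rng.random() < config.long_stay_fraction
    margin = 72 * 60 + 240 if long_stay else 0

    # provisional horizon: margin + two 72-h sensors + margin
    horizon = margin + 2 * 72 * 60 + 240 + margin
    mu = config.bg_mean + rng.normal(0.0, config.bg_between_sd)
    blood = simulate_blood_glucose(config, rng, horizon, mu=mu)
    interstitial = simulate_interstitial(blood, config.lag_min)
    path_start = EPOCH - margin * MINUTE

    covariates = None
    noise_scale = None
    if config.with_covariates:
        covariates = _simulate_covariates(rng, pid, path_start, horizon)
        if config.confounder_coupling > 0:
            sofa = covariates[covariates["name"] == "SOFA"]
            sofa_min = ((sofa["timestamp"] - path_start) / MINUTE).astype(int).to_numpy()
            vals = sofa["value"].to_numpy(dtype=float)
            per_min = np.interp(np.arange(horizon), sofa_min, vals)
            noise_scale = np.clip(
                1.0 + config.confounder_coupling * (per_min - 8.0) / 8.0, 0.2, None
            )

    sensors: list[SimulatedSensor] = []
    offset = margin  # first init at EPOCH
    sim = simulate_sensor(
        config, rng, interstitial, blood, offset, pid, f"{pid}S1",
        path_start + offset * MINUTE, noise_scale,
    )
    sensors.append(sim)
    monitored_h = sim.session.monitoring_minutes / 60.0
    if config.second_sensor_if_short and sim.premature and monitored_h < 48.0:
        gap_h = rng.uniform(1.0, 4.0)
        offset2 = offset + sim.session.monitoring_minutes + int(gap_h * 60)
        if offset2 + 12 * 60 < horizon - margin + 72 * 60:
            sim2 = simulate_sensor(
                config, rng, interstitial, blood, offset2, pid, f"{pid}S2",
                path_start + offset2 * MINUTE, noise_scale,
            )
            sensors.append(sim2)

    last_end = max(s.session.end_time for s in sensors)
    ref_start = path_start if long_stay else path_start + offset * MINUTE
    ref_end = (last_end + (72 * 60 + 120) * MINUTE) if long_stay else last_end
    ref_rows: dict[pd.Timestamp, GlucoseSample] = {}
    t = ref_start + int(rng.uniform(20, 60)) * MINUTE
    lo_h, hi_h = config.ref_interval_h
    while t <= ref_end:
        m = int((t - path_start) / MINUTE)
        if 0 <= m < horizon:
            src = Source.ARTERIAL if rng.random() < config.arterial_fraction else Source.VENOUS
            ref_rows[t] = GlucoseSample(t, float(blood[m]), src, pid)
        t = t + int(rng.uniform(lo_h * 60, hi_h * 60)) * MINUTE
    # calibration draws are blood draws too: they enter the reference log
    for s in sensors:
        for cal in s.session.calibrations:
            ref_rows.setdefault(
                cal.timestamp,
                GlucoseSample(cal.timestamp, cal.reference_value, Source.ARTERIAL, pid),
            )

    grid = pd.date_range(path_start, periods=horizon, freq="min")
    record = PatientRecord(
        patient_id=pid,
        sessions=[s.session for s in sensors],
        reference_samples=sorted(ref_rows.values(), key=lambda s: s.timestamp),
        covariates=covariates[["timestamp", "name", "value"]] if covariates is not None else None,
    )
    truth = SimulatedTruth(
        patient_id=pid,
        blood=pd.Series(blood, index=grid),
        interstitial=pd.Series(interstitial, index=grid),
        tau_min=config.lag_min,
        true_gaps={s.session.sensor_id: s.true_gaps for s in sensors},
        premature={s.session.sensor_id: s.premature for s in sensors},
        long_stay=long_stay,
    )
    return record, truth


def generate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate a full cohort; byte-reproducible from config.seed."""
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_patients)
    records: dict[str, PatientRecord] = {}
    truth: dict[str, SimulatedTruth] = {}
    for i, ps in enumerate(seeds):
        rec, tr = generate_patient(config, ps, i)
        records[rec.patient_id] = rec
        truth[rec.patient_id] = tr
    return SyntheticCohort(config, records, truth)
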