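# Methods

This note documents the models and procedures behind `cgmeval`: what each
analysis computes, what the synthetic cohort generator emulates (and does
not), the numerical conventions, and the design choices that were
genuinely open.

## Pair extraction

Point accuracy is defined on pairs of one reference blood-glucose value
and the latest sensor value at or before it. Conventions:

- **Pairing window: 5 min.** "Latest value immediately before" is
  unquantified in evaluation practice; at one reading per minute a 5-min
  window bounds staleness without discarding references that fall just
  after a missed minute. Overridable (`window_min`).
- **Same-minute ties** use the same-minute sensor value: at 1-min
  resolution "immediately before" includes the minute itself.
- **Calibration exclusions.** The first three calibrations of a session
  (start-up and the entries after the first and second running hour,
  identified by order) and any calibration preceded by a display gap of
  more than 15 missing minutes are excluded from accuracy: the device
  re-anchors on exactly these values, so pairing them would score the
  sensor against its own input. Routine 8-hourly calibration references
  *are* paired but carry an `is_calibration` flag so they can be filtered;
  whether they belong in the comparative set is genuinely ambiguous, and
  flagging preserves both analyses.
- **References with no running session** (before initialization, after
  removal, between sensors) are never paired but stay available to the
  glycemic-metrics and comparison analyses, which deliberately include
  draws taken during device downtime.
- Patients qualify for the accuracy analysis with ≥ 48 monitored hours or
  ≥ 12 comparative readings.

## Point accuracy

- **MARD CI**: normal approximation (mean ± 1.96 SE) by default; the
  percentile bootstrap (2000 resamples, seeded) is available behind a
  flag. The normal default keeps the report reproducible without a seed.
- **Consensus bands are inclusive** (≤ 12.5 %, ≤ 20 %): the boundary
  convention is unstated in the criteria, so the package fixes one and
  documents it; the helpers are small enough to swap.
- **Clarke zones** use the canonical piecewise-linear boundaries, with
  every inequality written out in `accuracy.clarke_zone` and each edge
  tested against an independently written region classifier
  (`tests/clarke_oracle.py`) on a full 600 × 600 mg/dl grid.
- **Surveillance-style risk surface**: the published continuous risk grid
  is distributed only as external software, so `cgmeval.seg` provides a
  *synthetic surrogate* with the documented structural properties rather
  than a bit-exact copy. Each glucose value maps through a
  piecewise-linear clinical-severity coordinate H (steep below 70 mg/dl,
  gentle across 70–180, moderate above); risk = clip(|H(sensor) −
  H(reference)|, 0, 4). The signed surface is bundled as a coarse anchor
  grid whose axes contain every breakpoint of H, so bilinear interpolation
  reproduces it exactly — in particular risk is exactly zero on the
  diagonal and monotone away from it, properties a non-separable coarse
  grid would lose under interpolation. Colour zones at 0.5/1.5/2.5/3.5.
  Quantitative risk values are surrogate-specific; only ordering and zone
  semantics should be interpreted.
- Percentages in reports are printed to one decimal, rounding half away
  from zero, as clinical tables do.

## Reliability

A gap is a maximal run of missing display minutes strictly inside the
monitoring span (init → removal); truncation at the end of a session is a
removal, not a gap — the two have separate cause taxonomies. Categories:
very brief < 15 min, brief 15–30, prolonged 31–120, very prolonged > 120.
The printed category labels ("15–30", "> 30", "> 2 h") leave the 30- and
120-min edges ambiguous; both edges are inclusive on the lower category
here and defined in one place (`reliability.CATEGORY_EDGES`).

Cause shares are computed over two denominators — total gap minutes and
total monitoring minutes — because both appear in evaluation practice.
The consensus display criterion (> 95 % display, device-related gaps
< 30 min) is evaluated against actual monitoring time by default
(configurable to the expected 72 h). Cohort medians/IQRs are always
computed per sensor first, never from pooled minutes.

## Glycemic metrics

Bands are inclusive integer ranges: ≤ 40, 41–70, 71–149, 150–179, > 179
mg/dl; the insulin-therapy target (80–149) is carried separately and never
mixed into the 71–149 analysis bands. Event counts follow the
"newly developed" rule: one event per entry into a band from outside, one
for a series starting inside.

**Time in range** joins consecutive samples piecewise-linearly and
measures band occupancy exactly, including edge-crossing times; this is
symmetric for rises and falls, unlike last-observation-carried-forward.
Because an intermittent 2–4-hourly series genuinely underdetermines the
trajectory, the discrete reading-share variant is also provided
(`method="readings"`) and the two are reported side by side where that
question matters.

**GLI** accumulates (Δg)²/Δt [h] over consecutive samples into 24-h
windows anchored at the series start; partial windows are scaled to 24 h
and windows averaged. The 24-h normalisation (rather than the index's
original per-week convention) matches how the metric is tabulated in ICU
evaluations. GLI is sampling-rate dependent by construction — a per-minute
CGM series accumulates many small steps where a 2-hourly series sees one
large one — so intermittent and continuous GLIs are compared as computed,
without correction, as in practice.

## Confounders and lag

- Glucose-range strata: < 80, 80–179, > 179 mg/dl on the reference value;
  ARD medians/IQR per stratum, Kruskal–Wallis across populated strata.
- Variability strata: each pair is assigned by whether its reference lies
  within one SD of that patient's *daily* mean reference glucose (24-h
  blocks anchored on the first monitoring minute). "Within the first vs
  second standard deviation" admits more than one reading; within-1-SD vs
  beyond-1-SD is the one implemented, recorded here as a package decision.
- Covariates are matched to pairs by nearest timestamp within 4 h
  (blood-gas cadence); continuous covariates via Spearman correlation of
  ARD, binary flags via rank-sum comparison. Raw p-values are reported
  with no multiplicity correction, matching field practice for exploratory
  confounder screens.
- **Time-shift scan**: for shift k, each shift-0-eligible reference at t
  is paired with the sensor value at t + k (sensor later than blood,
  testing an interstitial delay; negative k supported). Shift 0 reproduces
  the baseline MARD exactly. The argmin of MARD(k) estimates the lag, with
  a caveat derived in the test suite: for a mean-reverting glucose process
  with relaxation time T, the mismatch-minimising shift of a first-order
  lag τ lies *below* τ (≈ 0.6–0.7 τ for τ/T up to ~1/6, from the OU
  cross-covariance), so the scan recovers small lags well and
  under-estimates large ones. This is a property of the estimator on such
  signals, not an implementation artifact.

## Comparisons

Longitudinal: per-patient glycemic summaries from reference data in three
windows — exactly 72 h before the first sensor start, the actual
monitoring span, and exactly 72 h after the last sensor end (anchored on
actual removal, also when premature). A window counts as covered when its
reference data reach within 4 h (one draw interval) of both window edges;
patients lacking coverage are excluded and listed. Friedman across
windows, pairwise Wilcoxon post hoc (exact distribution below n = 25, else
asymptotic).

Parallel: patients whose per-patient MARD is below the threshold (default
14 %) contribute one intermittent-reference and one full-CGM summary over
the union of their sensor sessions; reference draws during display gaps
are included. Paired Wilcoxon per metric. With the threshold at infinity
all patients with pairs qualify; tightening it never grows the cohort.

## Synthetic cohort generator

The generator emulates the statistical structure of an ICU CGM evaluation
cohort; defaults are calibration targets taken from a published 20-patient
trial's tables, not claims of physiological fidelity.

| parameter | default | provenance / rationale |
|---|---|---|
| patients | 20 | published cohort size |
| set-point μ | 134 mg/dl | published per-patient mean glucose (133.8) |
| between-patient SD of μ | 10 mg/dl | spread implied by the published IQR of per-patient means |
| within-patient SD | 25 mg/dl | published reference SD (24.8) |
| OU relaxation time θ⁻¹ | 2 h | plausible ICU glucose autocorrelation scale |
| interstitial lag τ | 10 min | upper end of reported physiological delays |
| sensor noise σₛ | 8 mg/dl | ~6 % of the set-point, matching mid-teens cohort MARD order |
| gain drift | 0.01 h⁻¹ random-walk SD | slow drift between calibrations |
| reference interval | U(2, 4) h | ICU blood-gas routine |
| calibrations | 0, +1 h, +2 h, then 8-hourly; after gaps > 15 min | device schedule |
| gap rate | 0.116 h⁻¹ | 155 gaps / 1337.1 monitored hours |
| gap mixture | 43.9/22.6/17.4/16.1 % | published category shares; very-prolonged durations U(121, 540) min so the mixture mean matches ~75 min/gap |
| premature removal | p = 0.677, time U(4, 70) h | 21/31 sensors removed early |
| long-stay fraction | 0.5 | half the cohort has 72 h of reference data either side (10/20 patients) |

Blood glucose is an exactly-discretised Ornstein–Uhlenbeck process on the
1-min grid (stationary SD equals the target for any relaxation time);
interstitial glucose is a first-order lag of it (exact exponential
update: step inputs reach 63.2 % at τ). The sensor is gain(t) ×
interstitial + Gaussian noise. Two calibration models are provided:

- `calibration_mode="reference"` (default): the gain re-anchors so the
  sensor equals the blood reference at the calibration minute. When blood
  and interstitial diverge (lag, excursions), this bakes calibration error
  into the following segment — the realistic behaviour.
- `calibration_mode="exact"`: idealized calibration resets the gain to 1,
  so with noise and drift off the sensor tracks interstitial exactly.
  Used where an analysis needs the lag isolated from calibration error
  (e.g. the lag-recovery suite, where anchored calibration would make
  calibration-minute pairs agree perfectly at shift 0 and drag the argmin
  there).

A patient whose first sensor fails before 48 h receives a second sensor
after a 1–4-h pause, mirroring study practice and yielding ~30 sensors per
20 patients. Calibration draws are emitted into the reference log (they
are blood draws), and the truth bundle (latent paths, τ, exact gap list,
removal flags) is stored alongside the dataset for oracle tests.

**What the generator does not emulate**: meals, insulin dosing and their
feedback on glucose (no controller); non-Gaussian sensor error;
patient-specific lag variation; covariates causally linked to glucose
(covariates are autocorrelated noise, optionally coupled to sensor noise
via `confounder_coupling` to create recoverable effects). Passing tests
therefore demonstrate the correctness and statistical behaviour of the
*analysis machinery* under a plausible data-generating process — not the
clinical performance of any real device.

## Problem sizes and determinism

All randomness flows through `numpy` generators seeded from
`SimulationConfig.seed` (per-patient child streams via `SeedSequence`), so
cohorts are byte-reproducible. Test and acceptance runs use 20-patient
cohorts (≈ 4000–20000 minutes of paths per patient), which gives a few
hundred comparative pairs — the same order as the 532-pair published
analysis — while keeping the full suite to a few minutes on one CPU.

## Known limitations

- The surrogate risk surface is separable; real surveillance-grid risk is
  mildly asymmetric in (reference, sensor). Ordering and zones are
  faithful, absolute risk values are not.
- The lag-scan argmin is a biased estimator of τ on mean-reverting
  signals (see above); it is reported as-is, with the bias documented,
  rather than corrected.
- Gap causes are annotations, not inferred states; a merged run of missing
  minutes carries the cause of its first carve.
- Timestamps are floored to whole minutes throughout; sub-minute device
  behaviour is out of scope.
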