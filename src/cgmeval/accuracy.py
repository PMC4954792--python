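"""Point-accuracy statistics for paired reference/sensor readings.

Implements the headline CGM accuracy toolkit: MARD with a 95 % CI, the 2013
ICU consensus point-accuracy criteria (98 % of readings within 12.5 % of
reference — or within +-10 mg/dl below 100 mg/dl — the remainder within
20 %, and MARD < 14 %, with MARD > 18 % flagged as poor), Bland-Altman bias
and limits of agreement, Clarke error-grid zoning, a Surveillance-Error-Grid
style continuous risk score, and Spearman rank correlation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .pairing import PairedReading
from . import seg

CONSENSUS_TIGHT_PCT = 12.5       # relative band, % of reference
CONSENSUS_ABS_BAND_MGDL = 10.0   # absolute band below the low-glucose cut
CONSENSUS_LOW_GLUCOSE_MGDL = 100.0
CONSENSUS_WIDE_PCT = 20.0
CONSENSUS_MARD_PCT = 14.0
POOR_MARD_PCT = 18.0
CONSENSUS_TIGHT_SHARE = 98.0     # % of readings required inside the tight band


def _arrays(pairs: Sequence[PairedReading]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    ref = np.array([p.reference_value for p in pairs], dtype=float)
    sen = np.array([p.sensor_value for p in pairs], dtype=float)
    ards = np.array([p.ard for p in pairs], dtype=float)
    return ref, sen, ards


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero, as clinical tables print percentages."""
    factor = 10.0**ndigits
    return math.floor(abs(x) * factor + 0.5) / factor * (1.0 if x >= 0 else -1.0)


def mard(
    pairs: Sequence[PairedReading],
    ci: str = "normal",
    n_boot: int = 2000,
    seed: int | None = None,
) -> tuple[float, tuple[float, float] | None]:
    """Mean absolute relative difference (%) and its 95 % CI.

    The default CI is the normal approximation mean +- 1.96 SE; ``ci="bootstrap"``
    uses a seeded percentile bootstrap instead. With a single pair the point
    estimate is returned with CI None.
    """
    if len(pairs) == 0:
        raise ValueError("mard requires at least one pair")
    ards = np.array([p.ard for p in pairs], dtype=float)
    m = float(ards.mean())
    if len(ards) < 2:
        return m, None
    if ci == "normal":
        se = float(ards.std(ddof=1)) / math.sqrt(len(ards))
        return m, (m - 1.96 * se, m + 1.96 * se)
    if ci == "bootstrap":
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, len(ards), size=(n_boot, len(ards)))
        means = ards[idx].mean(axis=1)
        lo, hi = np.percentile(means, [2.5, 97.5])
        return m, (float(lo), float(hi))
    raise ValueError(f"unknown ci method {ci!r}")


def within_tight_band(reference: float, sensor: float) -> bool:
    """Consensus tight band: 12.5 % relative, or +-10 mg/dl when reference < 100."""
    if reference < CONSENSUS_LOW_GLUCOSE_MGDL:
        return (
            abs(reference - sensor) <= CONSENSUS_ABS_BAND_MGDL
            or abs(reference - sensor) <= CONSENSUS_TIGHT_PCT / 100.0 * reference
        )
    return abs(reference - sensor) <= CONSENSUS_TIGHT_PCT / 100.0 * reference


@dataclass(frozen=True)
class ConsensusVerdict:
    pct_within_tight: float   # share in the 12.5 % / +-10 mg/dl band
    pct_within_wide: float    # share within 20 %
    mard: float
    c1_tight_98: bool         # >=98 % in the tight band
    c2_rest_within_20: bool   # every remaining pair within 20 %
    c3_mard_below_14: bool
    poor_accuracy: bool       # MARD > 18 %

    @property
    def passed(self) -> bool:
        return self.c1_tight_98 and self.c2_rest_within_20 and self.c3_mard_below_14


def consensus_check(pairs: Sequence[PairedReading]) -> ConsensusVerdict:
    if len(pairs) == 0:
        raise ValueError("consensus_check requires at least one pair")
    ref, sen, ards = _arrays(pairs)
    tight = np.array([within_tight_band(r, s) for r, s in zip(ref, sen)])
    wide = ards <= CONSENSUS_WIDE_PCT
    pct_tight = float(tight.mean() * 100.0)
    pct_wide = float(wide.mean() * 100.0)
    m = float(ards.mean())
    return ConsensusVerdict(
        pct_within_tight=pct_tight,
        pct_within_wide=pct_wide,
        mard=m,
        c1_tight_98=pct_tight >= CONSENSUS_TIGHT_SHARE,
        c2_rest_within_20=bool(np.all(wide | tight)),
        c3_mard_below_14=m < CONSENSUS_MARD_PCT,
        poor_accuracy=m > POOR_MARD_PCT,
    )


def bland_altman(pairs: Sequence[PairedReading]) -> tuple[float, tuple[float, float]]:
    """Mean bias (reference - sensor) and bias +- 1.96 x sample SD of the diffs."""
    if len(pairs) < 2:
        raise ValueError("bland_altman requires at least two pairs")
    ref, sen, _ = _arrays(pairs)
    diff = ref - sen
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    return bias, (bias - 1.96 * sd, bias + 1.96 * sd)


# ---------------------------------------------------------------------------
# Clarke error grid
# ---------------------------------------------------------------------------

def clarke_zone(reference: float, sensor: float) -> str:
    """Assign a (reference, sensor) pair to Clarke error-grid zone A-E.

    Canonical piecewise-linear boundaries of the original grid, evaluated in
    priority order A, E, C, D, else B:

    * A: sensor within 20 % of reference, or both in the hypoglycemic corner
      (reference <= 70 and sensor <= 70).
    * E: opposite-treatment errors — reference >= 180 with sensor <= 70, or
      reference <= 70 with sensor >= 180.
    * C: overcorrection — 70 <= reference <= 290 with sensor >= reference + 110
      (upper-C), or 130 <= reference <= 180 with sensor <= 7/5*reference - 182
      (lower-C).
    * D: dangerous failure to detect — reference >= 240 with 70 <= sensor <= 180,
      or reference <= 175/3 with 70 <= sensor <= 180, or
      175/3 <= reference <= 70 with sensor >= 6/5*reference.
    * B: everything else (benign deviation > 20 %).
    """
    if reference <= 0 or sensor <= 0:
        raise ValueError("Clarke zones are defined for positive glucose values")
    r, s = float(reference), float(sensor)
    if (r <= 70 and s <= 70) or (0.8 * r <= s <= 1.2 * r):
        return "A"
    if (r >= 180 and s <= 70) or (r <= 70 and s >= 180):
        return "E"
    if (70 <= r <= 290 and s >= r + 110) or (130 <= r <= 180 and s <= (7.0 / 5.0) * r - 182):
        return "C"
    if (
        (r >= 240 and 70 <= s <= 180)
        or (r <= 175.0 / 3.0 and 70 <= s <= 180)
        or (175.0 / 3.0 <= r <= 70 and s >= (6.0 / 5.0) * r)
    ):
        return "D"
    return "B"


def clarke_distribution(pairs: Sequence[PairedReading]) -> dict[str, float]:
    """Percentage of pairs per zone A-E; sums to 100 up to rounding."""
    if len(pairs) == 0:
        raise ValueError("clarke_distribution requires at least one pair")
    counts = {z: 0 for z in "ABCDE"}
    for p in pairs:
        counts[clarke_zone(p.reference_value, p.sensor_value)] += 1
    n = len(pairs)
    return {z: counts[z] / n * 100.0 for z in "ABCDE"}


def seg_risk(reference: float, sensor: float) -> tuple[float, str]:
    """Surveillance-style continuous risk score (0-4) and its color zone."""
    return seg.risk(reference, sensor), seg.color_zone(seg.risk(reference, sensor))


def rank_correlation(pairs: Sequence[PairedReading]) -> tuple[float, float, float]:
    """Spearman rho between reference and sensor, two-sided p, and rho**2."""
    if len(pairs) < 3:
        raise ValueError("rank_correlation requires at least three pairs")
    ref, sen, _ = _arrays(pairs)
    if np.all(ref == ref[0]) or np.all(sen == sen[0]):
        raise ValueError("rank correlation undefined for constant input")
    rho, p = stats.spearmanr(ref, sen)
    return float(rho), float(p), float(rho) ** 2


@dataclass
class AccuracyReport:
    """Full point-accuracy summary for a set of comparative pairs."""

    n_pairs: int
    mard: float
    mard_ci95: tuple[float, float] | None
    consensus: ConsensusVerdict
    bias: float
    loa_lower: float
    loa_upper: float
    spearman_rho: float
    spearman_p: float
    r_squared: float
    clarke_distribution: dict[str, float]
    seg_mean_risk: float
    seg_zone_counts: dict[str, int]

    def summary(self) -> str:
        c = self.consensus
        ci = (
            f"({self.mard_ci95[0]:.1f}-{self.mard_ci95[1]:.1f})"
            if self.mard_ci95
            else "(n/a)"
        )
        lines = [
            "Point accuracy summary",
            "======================",
            f"comparative pairs        {self.n_pairs}",
            f"MARD (%)                 {self.mard:.1f}  95% CI {ci}",
            f"within 12.5%/10 mg/dl    {c.pct_within_tight:.1f}%   (consensus >=98%: {'pass' if c.c1_tight_98 else 'FAIL'})",
            f"within 20%               {c.pct_within_wide:.1f}%   (remainder rule: {'pass' if c.c2_rest_within_20 else 'FAIL'})",
            f"MARD < 14%               {'pass' if c.c3_mard_below_14 else 'FAIL'}"
            + ("   [poor accuracy: MARD > 18%]" if c.poor_accuracy else ""),
            f"consensus verdict        {'PASS' if c.passed else 'FAIL'}",
            f"Bland-Altman bias        {self.bias:+.2f} mg/dl, LoA {self.loa_upper:+.1f} / {self.loa_lower:+.1f}",
            f"Spearman rho             {self.spearman_rho:.3f} (p={self.spearman_p:.3g}, r^2={self.r_squared:.3f})",
            "Clarke zones (%)         "
            + "  ".join(f"{z} {self.clarke_distribution[z]:.1f}" for z in "ABCDE"),
            f"SEG mean risk            {self.seg_mean_risk:.2f}  zones "
            + " ".join(f"{z}:{n}" for z, n in self.seg_zone_counts.items() if n),
        ]
        return "\n".join(lines)


def accuracy_report(
    pairs: Sequence[PairedReading],
    ci: str = "normal",
    seed: int | None = None,
) -> AccuracyReport:
    """Compute every point-accuracy statistic on one set of pairs."""
    m, m_ci = mard(pairs, ci=ci, seed=seed)
    verdict = consensus_check(pairs)
    bias, (lo, hi) = bland_altman(pairs)
    rho, p, r2 = rank_correlation(pairs)
    risks = [seg.risk(q.reference_value, q.sensor_value) for q in pairs]
    zone_counts: dict[str, int] = {z: 0 for z in seg.ZONE_NAMES}
    for r in risks:
        zone_counts[seg.color_zone(r)] += 1
    return AccuracyReport(
        n_pairs=len(pairs),
        mard=m,
        mard_ci95=m_ci,
        consensus=verdict,
        bias=bias,
        loa_lower=lo,
        loa_upper=hi,
        spearman_rho=rho,
        spearman_p=p,
        r_squared=r2,
        clarke_distribution=clarke_distribution(pairs),
        seg_mean_risk=float(np.mean(risks)),
        seg_zone_counts=zone_counts,
    )
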