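import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import cgmeval as cg
from cgmeval import seg
from cgmeval.accuracy import round_half_up, within_tight_band

from clarke_oracle import clarke_zone_oracle
from conftest import make_pairs


class TestMard:
    def test_hand_arithmetic(self):
        pairs = make_pairs([(100, 100), (100, 85), (100, 80)])  # ARDs 0, 15, 20
        m, _ = cg.mard(pairs)
        assert round_half_up(m, 2) == 11.67

    def test_perfect_agreement_gives_zero_with_zero_width_ci(self):
        pairs = make_pairs([(100, 100), (150, 150), (80, 80)])
        m, (lo, hi) = cg.mard(pairs)
        assert m == 0.0 and lo == 0.0 and hi == 0.0

    def test_bootstrap_ci_is_seeded_and_brackets_estimate(self):
        pairs = make_pairs([(100, 90 + i) for i in range(15)])
        m, ci1 = cg.mard(pairs, ci="bootstrap", seed=42)
        _, ci2 = cg.mard(pairs, ci="bootstrap", seed=42)
        assert ci1 == ci2
        assert ci1[0] <= m <= ci1[1]

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            cg.mard([])

    def test_matches_bruteforce_mean_of_raw_ards(self, default_pairs):
        m, _ = cg.mard(default_pairs)
        brute = np.mean(
            [abs(p.reference_value - p.sensor_value) / p.reference_value * 100
             for p in default_pairs]
        )
        assert m == pytest.approx(brute, abs=1e-12)


class TestConsensus:
    def test_identical_pairs_pass_everything(self):
        v = cg.consensus_check(make_pairs([(120, 120)] * 5))
        assert v.passed and not v.poor_accuracy

    def test_absolute_band_below_100(self):
        # 80 vs 89: 11.25 % relative but only 9 mg/dl absolute -> inside band
        assert within_tight_band(80, 89)
        # 80 vs 91: 11 mg/dl; 13.75 % relative -> outside
        assert not within_tight_band(80, 91)

    def test_low_tight_share_fails_first_criterion(self):
        pairs = make_pairs([(100, 100)] * 6 + [(100, 118)] * 4)  # 60 % within 12.5 %
        v = cg.consensus_check(pairs)
        assert v.pct_within_tight == pytest.approx(60.0)
        assert not v.c1_tight_98 and not v.passed

    def test_poor_accuracy_flag(self):
        v = cg.consensus_check(make_pairs([(100, 75)] * 4))  # MARD 25 %
        assert v.poor_accuracy


class TestBlandAltman:
    def test_symmetric_diffs_zero_bias(self):
        bias, (lo, hi) = cg.bland_altman(make_pairs([(110, 100), (100, 110)]))
        assert bias == pytest.approx(0.0)
        assert hi == pytest.approx(1.96 * np.std([10, -10], ddof=1), abs=1e-9)
        assert round_half_up(hi, 2) == 27.72

    def test_antisymmetry_under_swap(self, default_pairs):
        bias, (lo, hi) = cg.bland_altman(default_pairs)
        swapped = [
            cg.PairedReading.make(p.patient_id, p.sensor_id, p.timestamp,
                                  p.sensor_value, p.reference_value, p.reference_source)
            for p in default_pairs
        ]
        # swapping roles changes the diff sign; ARD renormalisation does not matter here
        bias2, (lo2, hi2) = cg.bland_altman(swapped)
        assert bias2 == pytest.approx(-bias)
        assert lo2 == pytest.approx(-hi) and hi2 == pytest.approx(-lo)


class TestClarke:
    @pytest.mark.parametrize(
        "ref,sen,zone",
        [
            (100, 100, "A"),   # diagonal
            (60, 65, "A"),     # hypoglycemic corner
            (200, 60, "E"),    # hyper read as hypo
            (50, 200, "E"),    # hypo read as hyper
            (100, 220, "C"),   # overcorrection upper
            (150, 20, "C"),    # overcorrection lower
            (300, 120, "D"),   # missed hyperglycemia
            (50, 120, "D"),    # missed hypoglycemia
            (150, 190, "B"),
        ],
    )
    def test_canonical_zone_examples(self, ref, sen, zone):
        assert cg.clarke_zone(ref, sen) == zone

    def test_agreement_with_independent_oracle_on_coarse_grid(self):
        vals = np.arange(5, 601, 7)
        for r in vals:
            for s in vals:
                assert cg.clarke_zone(r, s) == clarke_zone_oracle(r, s), (r, s)

    def test_distribution_sums_to_100_and_contains_20pct_band(self, default_pairs):
        dist = cg.clarke_distribution(default_pairs)
        assert sum(dist.values()) == pytest.approx(100.0, abs=0.1)
        share_within_20 = np.mean([p.ard <= 20.0 for p in default_pairs]) * 100
        assert dist["A"] >= share_within_20 - 1e-9  # zone A is a superset

    def test_nonpositive_raises(self):
        with pytest.raises(ValueError):
            cg.clarke_zone(0, 100)


class TestSeg:
    @settings(derandomize=True, max_examples=60)
    @given(x=st.floats(min_value=20, max_value=600))
    def test_zero_on_diagonal(self, x):
        risk, zone = cg.seg_risk(x, x)
        assert risk == pytest.approx(0.0, abs=1e-12)
        assert zone == "none"

    def test_monotone_away_from_diagonal(self):
        risk_near, _ = cg.seg_risk(160, 150)
        risk_far, _ = cg.seg_risk(160, 70)
        assert 0 < risk_near < risk_far
        for ref in (45.0, 80.0, 130.0, 250.0, 480.0):
            sensors = np.linspace(ref, 600, 40)
            risks = [cg.seg_risk(ref, s)[0] for s in sensors]
            assert np.all(np.diff(risks) >= -1e-12)
            sensors = np.linspace(ref, 20, 40)
            risks = [cg.seg_risk(ref, s)[0] for s in sensors]
            assert np.all(np.diff(risks) >= -1e-12)

    def test_extreme_discordance_hits_top_zone(self):
        risk, zone = cg.seg_risk(40, 300)
        assert zone == "extreme" and risk == seg.RISK_MAX

    def test_out_of_domain_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            risk, _ = cg.seg_risk(700, 700)
        assert risk == pytest.approx(0.0)


class TestRankCorrelation:
    def test_monotone_and_reversed(self):
        up = make_pairs([(100 + i, 110 + 2 * i) for i in range(6)])
        rho, p, r2 = cg.rank_correlation(up)
        assert rho == pytest.approx(1.0)
        assert r2 == pytest.approx(1.0)
        down = make_pairs([(100 + i, 200 - 2 * i) for i in range(6)])
        assert cg.rank_correlation(down)[0] == pytest.approx(-1.0)

    def test_constant_input_raises(self):
        with pytest.raises(ValueError, match="constant"):
            cg.rank_correlation(make_pairs([(100, 90 + i) for i in range(5)]))


def test_full_report_on_noisy_cohort(default_pairs):
    report = cg.accuracy_report(default_pairs)
    assert report.n_pairs == len(default_pairs)
    assert report.consensus.pct_within_tight <= report.consensus.pct_within_wide <= 100.0
    assert report.loa_lower <= report.bias <= report.loa_upper
    text = report.summary()
    assert "MARD" in text and "Clarke" in text
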