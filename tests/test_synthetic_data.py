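import numpy as np
import pandas as pd
import pytest

import cgmeval as cg
from cgmeval.synthetic_data import (
    SimulationConfig,
    simulate_blood_glucose,
    simulate_interstitial,
)


class TestBloodGlucose:
    def test_zero_process_noise_gives_constant_path(self):
        cfg = SimulationConfig(bg_sd=0.0)
        path = simulate_blood_glucose(cfg, np.random.default_rng(0), 500, mu=134.0)
        assert np.allclose(path, 134.0)

    def test_stationary_sd_matches_target(self):
        # OU closed form: stationary SD equals bg_sd; check over many 72-h paths
        cfg = SimulationConfig()
        sds = [
            simulate_blood_glucose(cfg, np.random.default_rng(seed), 72 * 60).std()
            for seed in range(50)
        ]
        assert np.mean(sds) == pytest.approx(cfg.bg_sd, rel=0.10)

    def test_cohort_mean_near_setpoint(self, default_cohort):
        means = [t.blood.mean() for t in default_cohort.truth.values()]
        assert np.mean(means) == pytest.approx(134.0, abs=12.0)

    def test_nonpositive_setpoint_rejected(self):
        with pytest.raises(ValueError):
            simulate_blood_glucose(
                SimulationConfig(), np.random.default_rng(0), 100, mu=-5.0
            )


class TestInterstitial:
    def test_tau_zero_is_identity(self):
        path = np.array([100.0, 150, 120, 90])
        assert np.array_equal(simulate_interstitial(path, 0.0), path)

    @pytest.mark.parametrize("tau", [5.0, 10.0, 20.0])
    def test_step_response_63pct_at_tau(self, tau):
        n = 200
        blood = np.full(n, 150.0)
        blood[0] = 100.0  # step happens after minute 0
        out = simulate_interstitial(blood, tau)
        frac = (out[int(tau)] - 100.0) / 50.0
        assert frac == pytest.approx(1 - np.exp(-1), abs=1e-9)

    def test_sinusoid_amplitude_attenuation(self):
        tau, period = 10.0, 240.0
        omega = 2 * np.pi / period
        t = np.arange(20000)
        blood = 130 + 30 * np.sin(omega * t)
        out = simulate_interstitial(blood, tau)
        measured = (out[5000:].max() - out[5000:].min()) / 2.0
        predicted = 30.0 / np.sqrt(1 + (omega * tau) ** 2)
        assert measured == pytest.approx(predicted, rel=0.02)

    def test_negative_tau_rejected(self):
        with pytest.raises(ValueError):
            simulate_interstitial(np.ones(10), -1.0)


class TestCohortGeneration:
    def test_same_seed_gives_byte_identical_files(self, tmp_path):
        cfg = SimulationConfig(n_patients=2, seed=9)
        a = cg.generate_cohort(cfg)
        b = cg.generate_cohort(cfg)
        pa = a.write(tmp_path / "a")
        pb = b.write(tmp_path / "b")
        for key in pa:
            assert pa[key].read_bytes() == pb[key].read_bytes(), key

    def test_different_seeds_differ(self):
        a = cg.generate_cohort(SimulationConfig(n_patients=1, seed=1))
        b = cg.generate_cohort(SimulationConfig(n_patients=1, seed=2))
        sa = a.records["P01"].sessions[0].to_series()
        sb = b.records["P01"].sessions[0].to_series()
        assert not np.array_equal(sa.to_numpy()[:100], sb.to_numpy()[:100])

    def test_premature_removal_rate_near_published_share(self):
        # p = 0.677 over 31 independent single sensors -> about 21 removals
        cfg = SimulationConfig(
            n_patients=31, seed=13, second_sensor_if_short=False, long_stay_fraction=0.0
        )
        cohort = cg.generate_cohort(cfg)
        n_prem = sum(
            v for t in cohort.truth.values() for v in t.premature.values()
        )
        assert 14 <= n_prem <= 28  # 99.9 % binomial band around 21

    def test_sessions_validate_and_sensor_count_reasonable(self, default_cohort):
        for rec in default_cohort.records.values():
            assert 1 <= len(rec.sessions) <= 2
            for s in rec.sessions:
                assert cg.validate_session(s) == []

    def test_noiseless_sensor_equals_blood(self, noiseless_cohort):
        for pid, rec in noiseless_cohort.records.items():
            truth = noiseless_cohort.truth[pid]
            for session in rec.sessions:
                series = session.to_series()
                np.testing.assert_allclose(
                    series.to_numpy(), truth.blood[series.index].to_numpy()
                )

    def test_exact_calibration_mode_with_lag_tracks_interstitial(self):
        cfg = SimulationConfig(
            n_patients=1, seed=4, sensor_noise_sd=0.0, drift_sd_per_h=0.0,
            gap_rate_per_h=0.0, premature_removal_prob=0.0,
            second_sensor_if_short=False, calibration_mode="exact",
        )
        cohort = cg.generate_cohort(cfg)
        rec = cohort.records["P01"]
        truth = cohort.truth["P01"]
        series = rec.sessions[0].to_series()
        np.testing.assert_allclose(
            series.to_numpy(), truth.interstitial[series.index].to_numpy()
        )

    def test_reference_draw_cadence(self, default_cohort):
        # routine draws every 2-4 h: consecutive non-calibration intervals bounded
        for rec in default_cohort.records.values():
            times = rec.reference_series().index
            deltas = np.diff(times.view("int64")) / 60e9
            assert deltas.max() <= 4 * 60 + 1

    def test_calibration_schedule_starts_with_three_initials(self, default_cohort):
        for rec in default_cohort.records.values():
            for session in rec.sessions:
                cals = sorted(session.calibrations, key=lambda c: c.timestamp)
                assert cals[0].timestamp == session.init_time
                offsets = [
                    (c.timestamp - session.init_time) / pd.Timedelta(minutes=1)
                    for c in cals[:3]
                ]
                # +1 h and +2 h entries, allowing displacement past a gap
                assert offsets[1] >= 60 and offsets[2] >= 120


class TestMardMonotonicity:
    def test_cohort_mard_nondecreasing_in_noise(self):
        mards = []
        for sigma in (0.0, 4.0, 8.0):
            cfg = SimulationConfig(
                n_patients=4, seed=21, lag_min=0.0, sensor_noise_sd=sigma,
                drift_sd_per_h=0.0, gap_rate_per_h=0.0,
                premature_removal_prob=0.0, second_sensor_if_short=False,
            )
            pairs = cg.extract_all_pairs(cg.generate_cohort(cfg).records).pairs
            mards.append(cg.mard(pairs)[0])
        assert mards == sorted(mards)
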