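import numpy as np
import pandas as pd
import pytest

import cgmeval as cg
from cgmeval.confounders_lag import (
    covariate_correlations,
    mard_by_glucose_range,
    mard_by_variability_stratum,
    time_shift_mard,
)

from conftest import T0, MIN, make_pairs, make_session


class TestGlucoseRangeStrata:
    def test_perfect_midrange_pairs(self):
        pairs = make_pairs([(100 + i, 100 + i) for i in range(10)])
        res = mard_by_glucose_range(pairs)
        mid = next(s for s in res.strata if s.stratum == "80-179")
        assert mid.n_pairs == 10 and mid.mard_median == 0.0
        assert all(s.n_pairs == 0 for s in res.strata if s.stratum != "80-179")
        assert res.p_value is None  # only one populated stratum: no test

    def test_strata_partition_pairs(self, default_pairs):
        res = mard_by_glucose_range(default_pairs)
        assert sum(s.n_pairs for s in res.strata) == len(default_pairs)

    def test_proportional_noise_equalises_strata(self):
        # sensor error proportional to glucose: ARD identical in every stratum
        rng = np.random.default_rng(1)
        refs = rng.uniform(50, 300, 300)
        pairs = make_pairs([(r, r * 1.08) for r in refs])
        res = mard_by_glucose_range(pairs)
        meds = [s.mard_median for s in res.strata if s.n_pairs > 0]
        assert max(meds) - min(meds) < 1e-9


class TestVariabilityStrata:
    def test_references_at_daily_mean_land_in_first_stratum(self):
        session = make_session(range(0, 48 * 60), values=[120.0] * (48 * 60))
        refs = [
            cg.GlucoseSample(T0 + (60 + 180 * i) * MIN, 120.0, cg.Source.ARTERIAL, "P1")
            for i in range(15)
        ]
        rec = cg.PatientRecord("P1", [session], refs)
        pairs = cg.extract_pairs(rec).pairs
        res = mard_by_variability_stratum({"P1": rec}, pairs)
        within = next(s for s in res.strata if s.stratum == "within_1sd")
        assert within.n_pairs == len(pairs)

    def test_assignment_is_a_partition(self, default_cohort, default_pairs):
        res = mard_by_variability_stratum(default_cohort.records, default_pairs)
        assert (
            sum(s.n_pairs for s in res.strata) + res.n_unassigned == len(default_pairs)
        )


class TestCovariates:
    def _record_with_covariate(self, values, name="SOFA"):
        session = make_session(range(0, 24 * 60), values=[100.0] * (24 * 60))
        cov = pd.DataFrame(
            {
                "timestamp": [T0 + i * 60 * MIN for i in range(len(values))],
                "name": name,
                "value": values,
            }
        )
        refs = [
            cg.GlucoseSample(T0 + i * 60 * MIN, 100.0 + i, cg.Source.ARTERIAL, "P1")
            for i in range(len(values))
        ]
        return cg.PatientRecord("P1", [session], refs, covariates=cov)

    def test_monotone_covariate_ard_association(self):
        # sensor constant at 100 while reference climbs: ARD grows with the covariate
        rec = self._record_with_covariate(list(range(12)))
        pairs = cg.extract_pairs(rec).pairs
        (assoc,) = covariate_correlations({"P1": rec}, pairs)
        assert assoc.kind == "spearman"
        assert assoc.statistic == pytest.approx(1.0)

    def test_binary_covariate_uses_rank_sum(self):
        rec = self._record_with_covariate([0.0] * 6 + [1.0] * 6)
        pairs = cg.extract_pairs(rec).pairs
        (assoc,) = covariate_correlations({"P1": rec}, pairs)
        assert assoc.kind == "rank-sum"
        assert assoc.p_value is not None

    def test_absent_covariates_are_skipped_quietly(self, noiseless_cohort):
        records = {
            pid: cg.PatientRecord(pid, r.sessions, r.reference_samples, None)
            for pid, r in noiseless_cohort.records.items()
        }
        pairs = cg.extract_all_pairs(records).pairs
        assert covariate_correlations(records, pairs) == []


class TestTimeShift:
    def test_shift_zero_equals_baseline_mard(self, default_cohort):
        for rec in default_cohort.records.values():
            pairs = cg.extract_pairs(rec).pairs
            if not pairs:
                continue
            profile = time_shift_mard(rec, shifts=[0])
            assert profile.mard_at_shift[0] == pytest.approx(
                cg.mard(pairs)[0], abs=1e-12
            )
            assert profile.n_at_shift[0] == len(pairs)

    def test_constant_glucose_gives_flat_profile(self):
        cfg = cg.noiseless_config(n_patients=1, seed=2, bg_sd=0.0, bg_between_sd=0.0)
        cohort = cg.generate_cohort(cfg)
        rec = next(iter(cohort.records.values()))
        profile = time_shift_mard(rec, shifts=range(0, 15))
        assert max(profile.mard_at_shift) - min(profile.mard_at_shift) < 1e-9

    def test_lag_free_cohort_minimises_at_zero(self, noiseless_cohort):
        argmins = cg.cohort_lag_argmins(noiseless_cohort.records, shifts=range(0, 15))
        assert set(argmins.values()) == {0}

    def test_negative_shifts_supported(self, default_cohort):
        rec = next(iter(default_cohort.records.values()))
        profile = time_shift_mard(rec, shifts=range(-5, 6))
        assert profile.shifts[0] == -5 and profile.shifts[-1] == 5
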