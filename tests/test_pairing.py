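import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import cgmeval as cg
from cgmeval.io_model import CalibrationKind
from cgmeval.pairing import ard

from conftest import T0, MIN, make_session


def session_with_calibrations():
    """Continuous 12-h trace with the start/+1h/+2h then 8-hourly schedule."""
    cal = [(0, 110.0), (60, 112.0), (120, 114.0), (600, 118.0)]
    return make_session(range(0, 12 * 60), calibrations=cal)


class TestClassifyCalibration:
    def test_startup_entries_are_initial(self):
        s = session_with_calibrations()
        for event in s.calibrations[:3]:
            assert cg.classify_calibration(event, s) == CalibrationKind.INITIAL

    def test_8h_entry_with_continuous_display_is_scheduled(self):
        s = session_with_calibrations()
        assert cg.classify_calibration(s.calibrations[3], s) == CalibrationKind.SCHEDULED

    def test_calibration_after_20min_gap_is_post_gap(self):
        minutes = [m for m in range(0, 12 * 60) if not (580 <= m < 600)]
        s = make_session(
            minutes, calibrations=[(0, 110.0), (60, 111.0), (120, 112.0), (600, 115.0)]
        )
        assert cg.classify_calibration(s.calibrations[3], s) == CalibrationKind.POST_GAP

    def test_event_outside_session_raises(self):
        s = session_with_calibrations()
        bad = cg.CalibrationEvent(T0 + 20 * pd.Timedelta(hours=1), 100.0)
        with pytest.raises(ValueError, match="outside session"):
            cg.classify_calibration(bad, s)


class TestExtractPairs:
    def _record(self, session, refs):
        return cg.PatientRecord(
            "P1",
            [session],
            [cg.GlucoseSample(t, v, cg.Source.ARTERIAL, "P1") for t, v in refs],
        )

    def test_latest_preceding_sensor_value_and_ard(self):
        s = make_session(range(0, 200), values=[85.0] * 200)
        rec = self._record(s, [(T0 + 150 * MIN, 100.0)])
        ext = cg.extract_pairs(rec)
        (p,) = ext.pairs
        assert p.sensor_value == 85.0
        assert p.ard == pytest.approx(15.0)

    def test_same_minute_tie_uses_that_minute(self):
        s = make_session([0, 1, 2], values=[100.0, 90.0, 80.0])
        ext = cg.extract_pairs(self._record(s, [(T0 + 2 * MIN, 80.0)]))
        assert ext.pairs[0].sensor_value == 80.0

    def test_post_gap_and_initial_calibration_references_excluded(self):
        minutes = [m for m in range(0, 12 * 60) if not (580 <= m < 600)]
        s = make_session(
            minutes, calibrations=[(0, 110.0), (60, 111.0), (120, 112.0), (600, 115.0)]
        )
        refs = [(T0, 110.0), (T0 + 60 * MIN, 111.0), (T0 + 120 * MIN, 112.0),
                (T0 + 600 * MIN, 115.0)]
        ext = cg.extract_pairs(self._record(s, refs))
        assert ext.pairs == []
        assert ext.n_excluded_calibration == 4  # 3 initial + 1 post-gap

    def test_reference_inside_long_gap_is_unpairable(self):
        minutes = [m for m in range(0, 300) if not (100 <= m < 160)]
        s = make_session(minutes)
        ext = cg.extract_pairs(self._record(s, [(T0 + 130 * MIN, 100.0)]))
        assert ext.pairs == []
        assert ext.n_unpairable == 1

    def test_reference_outside_any_session_retained_but_unpaired(self):
        s = make_session(range(0, 100))
        ext = cg.extract_pairs(self._record(s, [(T0 + 500 * MIN, 100.0)]))
        assert ext.n_outside_sessions == 1
        assert ext.pairs == []

    def test_bookkeeping_partition(self, default_cohort):
        ext = cg.extract_all_pairs(default_cohort.records)
        assert (
            len(ext.pairs)
            + ext.n_excluded_calibration
            + ext.n_unpairable
            + ext.n_outside_sessions
            == ext.n_references
        )
        assert len(ext.pairs) <= ext.n_references

    def test_gap_free_cohort_pairs_every_eligible_reference(self, noiseless_cohort):
        ext = cg.extract_all_pairs(noiseless_cohort.records)
        assert ext.n_unpairable == 0
        assert len(ext.pairs) > 0


class TestInclusion:
    def _record_with(self, hours, n_refs, pid="P1"):
        n_min = int(hours * 60)
        s = make_session(range(0, n_min), values=[120.0] * n_min, patient_id=pid)
        step = max(1, (n_min - 10) // max(n_refs, 1))
        refs = [
            cg.GlucoseSample(T0 + (5 + i * step) * MIN, 120.0, cg.Source.ARTERIAL, pid)
            for i in range(n_refs)
        ]
        return cg.PatientRecord(pid, [s], refs)

    @pytest.mark.parametrize(
        "hours,n_refs,expected",
        [(50, 8, True), (24, 12, True), (24, 5, False)],
        ids=["48h-rule", "12-reading-rule", "neither"],
    )
    def test_inclusion_rules(self, hours, n_refs, expected):
        rec = self._record_with(hours, n_refs)
        (decision,) = cg.apply_inclusion({"P1": rec})
        assert decision.included is expected


@settings(derandomize=True, max_examples=50)
@given(
    ref=st.floats(min_value=20, max_value=600),
    sen=st.floats(min_value=20, max_value=600),
    c=st.floats(min_value=0.01, max_value=100),
)
def test_ard_scale_invariance(ref, sen, c):
    assert ard(ref * c, sen * c) == pytest.approx(ard(ref, sen), rel=1e-9)
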