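"""Cumulative-run segmentation and crisis-repair detection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from crisisrepair import (
    ConfigurationError,
    Course,
    VariabilityProfile,
    detect_crisis_repair,
    segment_runs,
)
from crisisrepair.crisis_repair import _scan_episodes

from oracles import crisis_repair_oracle, runs_by_groupby


def profile(sd: float, multiplier: int = 1) -> VariabilityProfile:
    return VariabilityProfile(sd, 0.0, multiplier, "intra_only")


class TestSegmentRuns:
    def test_single_direction_change(self):
        runs = segment_runs(Course.from_values("c", [60, 55, 50, 45, 40, 60]))
        assert [(r.kind, r.start_session, r.end_session, r.cumulative_change) for r in runs] == [
            ("decline", 1, 5, -20.0),
            ("incline", 5, 6, 20.0),
        ]

    def test_constant_course_is_one_degenerate_decline(self):
        runs = segment_runs(Course.from_values("c", [50, 50, 50]))
        assert [(r.kind, r.start_session, r.end_session, r.cumulative_change) for r in runs] == [
            ("decline", 1, 3, 0.0)
        ]

    def test_constants_inside_decline_belong_to_it(self):
        runs = segment_runs(Course.from_values("c", [60, 55, 55, 40, 70]))
        assert [(r.kind, r.start_session, r.end_session, r.cumulative_change) for r in runs] == [
            ("decline", 1, 4, -20.0),
            ("incline", 4, 5, 30.0),
        ]

    @settings(max_examples=200, deadline=None)
    @given(vals=st.lists(st.integers(0, 4).map(lambda k: 10.0 * k), min_size=3, max_size=10))
    def test_runs_partition_steps_and_match_groupby_oracle(self, vals):
        course = Course.from_values("c", vals)
        runs = segment_runs(course)
        # concatenating runs reproduces the step sequence without gaps
        assert runs[0].start_session == 1
        assert runs[-1].end_session == len(vals)
        for a, b in zip(runs, runs[1:]):
            assert a.end_session == b.start_session
            assert a.kind != b.kind
        assert [
            (r.kind, r.start_session - 1, r.end_session - 1, r.cumulative_change)
            for r in runs
        ] == runs_by_groupby(vals)
        for r in runs:
            steps = [vals[i] - vals[i - 1] for i in range(r.start_session, r.end_session)]
            if r.kind == "decline":
                assert all(s <= 0 for s in steps)
                assert r.cumulative_change <= 0
            else:
                assert all(s > 0 for s in steps)


class TestDetection:
    def test_gradual_slide_detected(self):
        c = Course.from_values("c", [60, 55, 50, 45, 40, 60])
        (ep,) = detect_crisis_repair(c, profile(15.0))
        assert (ep.start_session, ep.trough_session, ep.repair_session) == (1, 5, 6)
        assert ep.rupture_magnitude == pytest.approx(20.0)
        assert (ep.decline_length, ep.repair_length) == (4, 1)
        assert ep.repaired

    def test_single_step_v(self):
        c = Course.from_values("c", [60, 40, 60])
        (ep,) = detect_crisis_repair(c, profile(15.0))
        assert (ep.decline_length, ep.repair_length) == (1, 1)

    def test_constant_course_yields_nothing(self):
        assert detect_crisis_repair(Course.from_values("c", [50] * 8), profile(15.0)) == []

    def test_leading_constants_shift_start_and_flag(self):
        c = Course.from_values("c", [50, 50, 30, 50, 50])
        (ep,) = detect_crisis_repair(c, profile(10.0))
        assert (ep.start_session, ep.trough_session, ep.repair_session) == (2, 3, 4)
        assert ep.has_leading_constants

    def test_trough_takes_trailing_constants(self):
        # constants after the minimum belong to the rupture, lengthening the decline
        c = Course.from_values("c", [60, 30, 30, 30, 60])
        (ep,) = detect_crisis_repair(c, profile(20.0))
        assert (ep.start_session, ep.trough_session, ep.repair_session) == (1, 4, 5)
        assert (ep.decline_length, ep.repair_length) == (3, 1)

    def test_exact_threshold_depth_not_repaired_at_own_trough(self):
        # decline of exactly 1 SD: the trough itself lies on the repair band
        # but repair needs an upward step first
        c = Course.from_values("c", [60, 45, 45, 60])
        (ep,) = detect_crisis_repair(c, profile(15.0))
        assert ep.trough_session == 3  # trailing constant joins the decline
        assert ep.repair_session == 4

    def test_partial_recovery_merges_into_complex_episode(self):
        c = Course.from_values("c", [50, 30, 38, 20, 50])
        (ep,) = detect_crisis_repair(c, profile(10.0))
        assert (ep.start_session, ep.trough_session, ep.repair_session) == (1, 4, 5)
        assert len(ep.qualifying_decline_starts) == 2

    def test_unrepaired_at_course_end_reported_not_excluded(self):
        c = Course.from_values("c", [60, 60, 20, 20, 25])
        (ep,) = detect_crisis_repair(c, profile(20.0))
        assert not ep.repaired
        assert ep.repair_session is None
        assert ep.trough_session == 4

    def test_multiplier_validation(self):
        c = Course.from_values("c", [60, 40, 60])
        with pytest.raises(ConfigurationError):
            detect_crisis_repair(c, profile(10.0), multiplier=3)


class TestInvariants:
    @settings(max_examples=300, deadline=None)
    @given(vals=st.lists(st.integers(0, 4).map(lambda k: 10.0 * k), min_size=3, max_size=8))
    def test_scan_equals_literal_oracle_on_grid(self, vals):
        got = [(s, t, r) for s, t, r, _q, _l in _scan_episodes(vals, 15.0)]
        assert got == crisis_repair_oracle(vals, 15.0)

    @settings(max_examples=150, deadline=None)
    @given(
        # integer-valued floats keep the arithmetic exact under shifting
        vals=st.lists(st.integers(-50, 50).map(float), min_size=3, max_size=20),
        shift=st.integers(-100, 100).map(float),
    )
    def test_shift_invariance(self, vals, shift):
        th = 12.0
        a = _scan_episodes(vals, th)
        b = _scan_episodes([v + shift for v in vals], th)
        assert [(s, t, r) for s, t, r, _q, _l in a] == [
            (s, t, r) for s, t, r, _q, _l in b
        ]

    @settings(max_examples=200, deadline=None)
    @given(vals=st.lists(st.floats(0, 100), min_size=3, max_size=25))
    def test_threshold_nesting_and_episode_wellformedness(self, vals):
        c = Course.from_values("c", vals)
        p1 = profile(11.0, 1)
        eps1 = detect_crisis_repair(c, p1, multiplier=1)
        eps2 = detect_crisis_repair(c, p1, multiplier=2)
        starts1 = {q for e in eps1 for q in e.qualifying_decline_starts}
        starts2 = {q for e in eps2 for q in e.qualifying_decline_starts}
        assert starts2 <= starts1
        for eps, mult in ((eps1, 1), (eps2, 2)):
            prev_end = 0
            for e in eps:
                assert e.rupture_magnitude >= mult * 11.0
                assert e.start_session < e.trough_session
                if e.repaired:
                    assert e.trough_session < e.repair_session
                # episodes never overlap (boundary sessions may be shared)
                assert e.start_session >= prev_end
                prev_end = e.repair_session or len(vals)

    @settings(max_examples=200, deadline=None)
    @given(vals=st.lists(st.floats(0, 100), min_size=3, max_size=25))
    def test_big_single_steps_lie_inside_flagged_runs(self, vals):
        th = 20.0
        c = Course.from_values("c", vals)
        eps = detect_crisis_repair(c, profile(th))
        covered = set()
        for e in eps:
            end = e.repair_session or c.n_sessions
            covered.update(range(e.start_session, end + 1))
        for i in range(1, len(vals)):
            if vals[i - 1] - vals[i] >= th:
                assert {i, i + 1} <= covered
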