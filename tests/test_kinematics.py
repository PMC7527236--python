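import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from quadgait import (InsufficientDataError, MissingDataError,
                      UndefinedStatisticError, base_of_support_angle,
                      interior_angle, joint_angles, peak_timing_phase,
                      range_of_motion, trunk_angle)
from quadgait.io import Marker, MarkerTrack
from quadgait.kinematics import AngleName, AngleTrace
from quadgait.synth import simulate_angle_traces


def _rigid(points, theta, scale, offset):
    rot = np.array([[np.cos(theta), -np.sin(theta)],
                    [np.sin(theta), np.cos(theta)]])
    return [scale * rot @ np.asarray(p, dtype=float) + np.asarray(offset)
            for p in points]


class TestInteriorAngle:
    def test_collinear_is_180(self):
        assert interior_angle([1, 0], [0, 0], [2, 0]) == pytest.approx(180.0)

    def test_right_angle(self):
        assert interior_angle([0, 0], [1, 0], [0, 1]) == pytest.approx(90.0)

    def test_tabulated_coordinates_match_arccos_oracle(self):
        vertex, a, b = np.array([1.0, 2.0]), np.array([4.0, 6.0]), np.array([-2.0, 3.0])
        u, v = a - vertex, b - vertex
        expected = np.degrees(np.arccos(
            np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))))
        assert interior_angle(vertex, a, b) == pytest.approx(expected, abs=1e-9)

    def test_coincident_points_give_nan(self):
        assert np.isnan(interior_angle([0, 0], [0, 0], [1, 1]))

    @given(theta=st.floats(0, 2 * np.pi), scale=st.floats(0.1, 10),
           dx=st.floats(-50, 50), dy=st.floats(-50, 50))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_invariance_under_rigid_transform_and_scaling(self, theta, scale, dx, dy):
        pts = [[1.0, 2.0], [4.0, 6.0], [-2.0, 3.0]]
        base = interior_angle(*pts)
        moved = _rigid(pts, theta, scale, [dx, dy])
        assert interior_angle(*moved) == pytest.approx(base, abs=1e-7)


class TestJointAngles:
    def _tracks(self, crest, hip, ankle, toe, n=10, rate=100.0):
        def track(marker, p):
            return MarkerTrack(marker, rate, np.tile(np.asarray(p, float), (n, 1)))
        return {Marker.ILIAC_CREST: track(Marker.ILIAC_CREST, crest),
                Marker.HIP: track(Marker.HIP, hip),
                Marker.ANKLE: track(Marker.ANKLE, ankle),
                Marker.TOE: track(Marker.TOE, toe)}

    def test_static_configuration(self):
        tracks = self._tracks([0, 4], [0, 2], [2, 2], [2, 0])
        trace = joint_angles(tracks, 0.0, 0.05)
        # hip: crest straight up, ankle to the right -> 90 deg
        np.testing.assert_allclose(trace.proximal_deg, 90.0, atol=1e-9)
        # ankle: hip to the left, toe straight down -> 90 deg
        np.testing.assert_allclose(trace.distal_deg, 90.0, atol=1e-9)

    def test_missing_marker_rejected(self):
        tracks = self._tracks([0, 4], [0, 2], [2, 2], [2, 0])
        del tracks[Marker.TOE]
        with pytest.raises(MissingDataError, match="toe"):
            joint_angles(tracks, 0.0, 0.05)

    def test_coincident_frames_dropped(self):
        tracks = self._tracks([0, 4], [0, 2], [2, 2], [2, 0])
        tracks[Marker.ANKLE] = MarkerTrack(
            Marker.ANKLE, 100.0,
            np.vstack([[0.0, 2.0], np.tile([2.0, 2.0], (9, 1))]))  # frame 0 on hip
        trace = joint_angles(tracks, 0.0, 0.09)
        assert trace.times.size == 9


class TestRangeOfMotion:
    def test_constant_angle_zero_excursion(self):
        trace = AngleTrace("s", np.linspace(0, 1, 20), np.full(20, 100.0),
                           np.full(20, 80.0))
        prox, dist = range_of_motion(trace)
        assert prox.excursion_deg == 0.0
        assert dist.excursion_deg == 0.0

    def test_sinusoid_excursion_is_twice_amplitude(self):
        t = np.linspace(0, 1, 400)
        trace = AngleTrace("s", t, 100 + 15 * np.sin(2 * np.pi * t),
                           90 + 25 * np.sin(2 * np.pi * t))
        prox, dist = range_of_motion(trace)
        assert prox.excursion_deg == pytest.approx(30.0, abs=0.01)
        assert dist.excursion_deg == pytest.approx(50.0, abs=0.01)

    def test_generator_amplitudes_recovered(self):
        traces = simulate_angle_traces([(0.0, 0.4)], frame_rate=500.0,
                                       proximal_amp=20.0, distal_amp=35.0)
        prox, dist = range_of_motion(traces[0])
        assert prox.excursion_deg == pytest.approx(40.0, abs=0.1)
        assert dist.excursion_deg == pytest.approx(70.0, abs=0.1)

    def test_excursion_subadditive_over_concatenation(self):
        rng = np.random.default_rng(0)
        t = np.linspace(0, 1, 100)
        a = 100 + rng.normal(0, 5, 100)
        trace = AngleTrace("s", t, a, a)
        first = AngleTrace("s1", t[:50], a[:50], a[:50])
        second = AngleTrace("s2", t[50:], a[50:], a[50:])
        whole = range_of_motion(trace)[0].excursion_deg
        assert whole >= range_of_motion(first)[0].excursion_deg - 1e-12
        assert whole >= range_of_motion(second)[0].excursion_deg - 1e-12

    def test_empty_trace_rejected(self):
        with pytest.raises(InsufficientDataError):
            range_of_motion(AngleTrace("s", np.array([]), np.array([]), np.array([])))


class TestPeakTimingPhase:
    def test_coincident_peaks_in_phase(self):
        traces = simulate_angle_traces([(0.0, 0.5)], frame_rate=1000.0, lag=0.0)
        assert peak_timing_phase(traces[0], 0.5) == pytest.approx(0.0, abs=2e-3)

    def test_half_stride_lag(self):
        t = np.linspace(0, 1, 1001)
        trace = AngleTrace("s", t, 100 + 10 * np.cos(2 * np.pi * t),
                           100 + 10 * np.cos(2 * np.pi * (t - 0.5)))
        assert peak_timing_phase(trace, 1.0) == pytest.approx(0.5, abs=1e-3)

    def test_imposed_lag_recovered_within_quantization(self):
        rate = 500.0
        traces = simulate_angle_traces([(0.0, 0.4)], frame_rate=rate, lag=0.12)
        phase = peak_timing_phase(traces[0], 0.4)
        assert phase == pytest.approx(0.12, abs=1.0 / (rate * 0.4))

    def test_trace_against_itself_is_zero(self):
        t = np.linspace(0, 1, 200)
        a = 100 + 10 * np.cos(2 * np.pi * (t - 0.6))
        assert peak_timing_phase(AngleTrace("s", t, a, a.copy()), 1.0) == 0.0

    def test_flat_trace_has_no_peak(self):
        t = np.linspace(0, 1, 50)
        with pytest.raises(UndefinedStatisticError):
            peak_timing_phase(AngleTrace("s", t, np.full(50, 90.0),
                                         100 + 10 * np.sin(t)), 1.0)


class TestBaseOfSupport:
    def test_paw_on_midline_extension(self):
        assert base_of_support_angle([0, 10], [0, 5], [0, 0]) == pytest.approx(0.0)

    def test_paw_perpendicular_to_body_axis(self):
        assert base_of_support_angle([0, 10], [0, 5], [3, 5]) == pytest.approx(90.0)

    def test_constructed_30_degree_geometry(self):
        # body axis pointing down (-y); paw 30 deg off the caudal extension
        paw = [np.sin(np.radians(30.0)), 5 - np.cos(np.radians(30.0))]
        assert base_of_support_angle([0, 10], [0, 5], paw) == pytest.approx(
            30.0, abs=1e-9)

    def test_coincident_points_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            base_of_support_angle([0, 5], [0, 5], [1, 1])


class TestTrunkAngle:
    def test_body_parallel_to_surface(self):
        assert trunk_angle([0, 0], [10, 0], [2, 3], [6, 3]) == pytest.approx(0.0)

    def test_45_degree_inclination(self):
        assert trunk_angle([0, 0], [10, 0], [0, 0], [2, 2]) == pytest.approx(45.0)

    def test_result_is_acute(self):
        assert trunk_angle([0, 0], [10, 0], [2, 2], [0, 0]) == pytest.approx(45.0)

    def test_rotation_invariance(self):
        pts = [[0, 0], [10, 0], [0, 0], [3, 2]]
        base = trunk_angle(*pts)
        for theta in (0.3, 1.2, 2.9):
            assert trunk_angle(*_rigid(pts, theta, 1.0, [5, -2])) == pytest.approx(
                base, abs=1e-9)

    def test_degenerate_surface_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            trunk_angle([1, 1], [1, 1], [0, 0], [1, 0])
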