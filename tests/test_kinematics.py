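"""Midline kinematics: angles, filtering, half cycles, classification,
propagation and yaw."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tadstruggle import kinematics as kin
from tadstruggle import synthetic as sy

from conftest import circle_body


def _body_from_points(pts, frame_rate=240.0):
    pts = np.asarray(pts, dtype=float)[None]
    return kin.TrackedBody(times=np.array([0.0]), points=pts,
                           frame_rate=frame_rate, body_length=5.0)


class TestCurvatureAngles:
    def test_straight_body_gives_zero_angles(self):
        pts = np.stack([np.linspace(0, 5, 11), np.zeros(11)], axis=1)
        a = kin.compute_curvature_angles(_body_from_points(pts))
        assert np.allclose(a.angles, 0.0)
        assert np.allclose(a.sum_trace, 0.0)

    def test_right_angle_magnitude(self):
        # one vertex turns left by 90 degrees: a=(1,0), b=(0,1)
        pts = [(i, 0.0) for i in range(6)] + [(5.0, j) for j in range(1, 6)]
        a = kin.compute_curvature_angles(_body_from_points(pts))
        assert a.angles[0, 4] == pytest.approx(np.pi / 2, abs=1e-12)

    @pytest.mark.parametrize("rotation", [0.0, 0.7, 2.1])
    @pytest.mark.parametrize("radius", [0.5, 1.0, 3.0])
    def test_full_circle_polyline(self, rotation, radius):
        # inscribed equilateral polyline: each exterior angle is 2*pi/10,
        # so the sum is 9/10 of a full turn, whatever the radius/rotation
        a = kin.compute_curvature_angles(circle_body(radius=radius,
                                                     rotation=rotation))
        assert np.allclose(np.abs(a.angles), 2 * np.pi / 10, atol=1e-9)
        assert np.allclose(np.abs(a.sum_trace), 9 * 2 * np.pi / 10,
                           atol=1e-8)

    def test_coincident_points_flagged_not_zero(self):
        pts = np.stack([np.linspace(0, 5, 11), np.zeros(11)], axis=1)
        pts[4] = pts[3]  # coincident consecutive points
        a = kin.compute_curvature_angles(_body_from_points(pts))
        assert np.all(np.isnan(a.angles[0]))
        assert not a.valid[0]

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_signed_angle_magnitude_matches_arccos(self, seed):
        rng = np.random.default_rng(seed)
        pts = np.cumsum(rng.normal(0.5, 0.2, (11, 2)), axis=0)
        a = kin.compute_curvature_angles(_body_from_points(pts))
        av = pts[1:10] - pts[0:9]
        bv = pts[2:11] - pts[1:10]
        cosang = np.einsum("ij,ij->i", av, bv) / (
            np.linalg.norm(av, axis=1) * np.linalg.norm(bv, axis=1))
        expect = np.arccos(np.clip(cosang, -1, 1))
        assert np.allclose(np.abs(a.angles[0]), expect, atol=1e-9)

    def test_sum_trace_is_sum_of_angles_after_filtering(self, struggle_angles):
        assert np.allclose(struggle_angles.sum_trace,
                           struggle_angles.angles.sum(axis=1), atol=1e-12)


class TestLowpass:
    @staticmethod
    def _angle_set(trace, fs=240.0):
        n = trace.size
        angles = np.tile(trace[:, None], (1, 9)) / 9.0
        return kin.AngleSet(times=np.arange(n) / fs, angles=angles,
                            sum_trace=trace.copy(),
                            vertex_positions=np.linspace(0.5, 4.5, 9),
                            frame_rate=fs)

    def test_constant_trace_unchanged(self):
        aset = self._angle_set(np.full(512, 2.0))
        out = kin.lowpass_sum(aset)
        assert np.allclose(out.sum_trace, 2.0, atol=1e-9)

    def test_passband_and_stopband(self):
        t = np.arange(2048) / 240.0
        slow = np.sin(2 * np.pi * 5 * t)
        fast = np.sin(2 * np.pi * 100 * t)
        out = kin.lowpass_sum(self._angle_set(slow + fast), cutoff=50.0)
        # 5 Hz passes almost untouched; project onto each component
        gain_slow = np.dot(out.sum_trace, slow) / np.dot(slow, slow)
        gain_fast = np.dot(out.sum_trace, fast) / np.dot(fast, fast)
        assert abs(gain_slow - 1.0) < 0.01
        assert abs(gain_fast) < 0.10

    def test_cutoff_at_nyquist_rejected(self):
        with pytest.raises(ValueError):
            kin.lowpass_sum(self._angle_set(np.zeros(64)), cutoff=120.0)

    def test_original_retained(self):
        aset = self._angle_set(np.sin(np.arange(512)))
        before = aset.sum_trace.copy()
        kin.lowpass_sum(aset)
        assert np.array_equal(aset.sum_trace, before)
        assert not aset.filtered


class TestHalfCycles:
    def test_sinusoid_duration_and_amplitude(self):
        t = np.arange(0, 2.0, 1 / 1000.0)
        cycles = kin.detect_half_cycles(1.7 * np.sin(2 * np.pi * 7 * t), t)
        assert len(cycles) >= 20
        durs = [c.duration for c in cycles]
        amps = [c.amplitude for c in cycles]
        assert np.mean(durs) == pytest.approx(1000.0 / 14.0, rel=0.02)
        assert np.mean(amps) == pytest.approx(1.7, rel=0.02)
        sides = [c.side for c in cycles]
        assert all(a != b for a, b in zip(sides, sides[1:]))

    def test_constant_trace_empty(self):
        t = np.arange(100) / 240.0
        assert kin.detect_half_cycles(np.full(100, 3.0), t) == []

    def test_struggling_preset_recovery(self, struggle_angles):
        cycles = kin.detect_half_cycles(struggle_angles.sum_trace,
                                        struggle_angles.times)
        assert np.mean([c.duration for c in cycles]) == pytest.approx(
            125.0, rel=0.05)
        assert np.mean([c.amplitude for c in cycles]) == pytest.approx(
            2.4, rel=0.05)


def _prop(speed, synchronous=False, p=1e-6):
    return kin.PropagationEstimate(speed=speed, regression_p=p,
                                   n_lags=9, synchronous=synchronous)


class TestClassify:
    def test_initial_coiling(self):
        hc = [kin.HalfCycle(0, 0.183, 183.0, 4.1, 1)]
        out = kin.classify_movement(hc, _prop(np.nan, synchronous=True))
        assert out.label == "initial_coiling"

    def test_struggling(self):
        hc = [kin.HalfCycle(0, 0.071, 71.0, 2.4, 1)]
        assert kin.classify_movement(hc, _prop(42.5)).label == "struggling"

    def test_swimming(self):
        hc = [kin.HalfCycle(0, 0.025, 25.0, 1.0, 1)]
        assert kin.classify_movement(hc, _prop(-156.0)).label == "swimming"

    def test_transitional_after_release(self):
        hc = [kin.HalfCycle(0, 0.1, 100.0, 4.0, 1)]
        out = kin.classify_movement(hc, _prop(-218.0), after_release=True)
        assert out.label == "transitional_coiling"

    def test_ambiguous_reports_distances(self):
        # struggling-band amplitude but rostrocaudal propagation
        hc = [kin.HalfCycle(0, 0.05, 50.0, 2.0, 1)]
        out = kin.classify_movement(hc, _prop(-150.0))
        assert out.label == "unclassified"
        assert set(out.distances) == {"coiling", "struggling", "swimming"}

    def test_amplitude_ordering_on_presets(self):
        amps = {}
        for name in ("initial_coiling", "struggling", "swimming"):
            body, _ = sy.make_tracked_movement(sy.movement_preset(name,
                                                                  seed=5))
            aset = kin.lowpass_sum(kin.compute_curvature_angles(body))
            hcs = kin.detect_half_cycles(aset.sum_trace, aset.times)
            amps[name] = np.mean([h.amplitude for h in hcs])
        assert (amps["initial_coiling"] > amps["struggling"]
                > amps["swimming"])


class TestPropagation:
    def test_imposed_struggling_speed_recovered(self, struggle_angles):
        p = kin.propagation_speed(struggle_angles)
        assert not p.synchronous
        assert p.regression_p < 0.001
        assert p.speed == pytest.approx(42.5, rel=0.05)

    def test_identical_traces_synchronous(self):
        t = np.arange(512) / 240.0
        trace = np.sin(2 * np.pi * 4 * t)
        aset = kin.AngleSet(times=t, angles=np.tile(trace[:, None], (1, 9)),
                            sum_trace=9 * trace,
                            vertex_positions=np.linspace(0.5, 4.5, 9),
                            frame_rate=240.0)
        assert kin.propagation_speed(aset).synchronous

    def test_reversed_swimming_wave_negative(self):
        body, _ = sy.make_tracked_movement(sy.movement_preset("swimming",
                                                              seed=2))
        aset = kin.lowpass_sum(kin.compute_curvature_angles(body))
        p = kin.propagation_speed(aset)
        assert p.speed == pytest.approx(-156.0, rel=0.05)

    def test_time_reversal_negates_speed(self, struggle_angles):
        import dataclasses
        rev = dataclasses.replace(
            struggle_angles, angles=struggle_angles.angles[::-1].copy(),
            sum_trace=struggle_angles.sum_trace[::-1].copy())
        p_fwd = kin.propagation_speed(struggle_angles)
        p_rev = kin.propagation_speed(rev)
        assert p_rev.speed == pytest.approx(-p_fwd.speed, rel=0.02)

    def test_head_tail_relabel_negates_speed(self, struggle_angles):
        import dataclasses
        flipped = dataclasses.replace(
            struggle_angles, angles=struggle_angles.angles[:, ::-1].copy())
        p_fwd = kin.propagation_speed(struggle_angles)
        p_flip = kin.propagation_speed(flipped)
        assert p_flip.speed == pytest.approx(-p_fwd.speed, rel=0.05)


class TestCurvatureOrigin:
    def test_bidirectional_wave_origin_and_branches(self):
        spec = sy.WaveSpec(frequency=4.0, amplitude=2.4,
                           propagation_speed=42.5, origin=0.70,
                           caudal_speed=23.9, duration=2.0, seed=2)
        body, _ = sy.make_tracked_movement(spec)
        aset = kin.lowpass_sum(kin.compute_curvature_angles(body))
        o = kin.find_curvature_origin(aset)
        assert o.defined
        assert o.origin_fraction == pytest.approx(0.70, abs=0.05)
        assert o.caudal_propagation
        assert o.caudal_speed == pytest.approx(-23.9, rel=0.10)
        assert o.rostral_speed == pytest.approx(42.5, rel=0.10)

    def test_unidirectional_wave_undefined(self, struggle_angles):
        o = kin.find_curvature_origin(struggle_angles)
        assert not o.defined


class TestYaw:
    def test_rigid_rotation_peak_to_peak(self):
        t = np.arange(256) / 240.0
        heading = np.radians(15.0) * np.sin(2 * np.pi * 4 * t)
        base = np.stack([np.linspace(0, 5, 11), np.zeros(11)], axis=1)
        rot = np.stack([
            np.stack([np.cos(h) * base[:, 0] - np.sin(h) * base[:, 1],
                      np.sin(h) * base[:, 0] + np.cos(h) * base[:, 1]],
                     axis=1) for h in heading])
        body = kin.TrackedBody(times=t, points=rot, frame_rate=240.0,
                               body_length=5.0)
        assert kin.compute_yaw(body) == pytest.approx(30.0, abs=0.1)

    def test_translation_without_rotation_zero(self):
        t = np.arange(64) / 240.0
        base = np.stack([np.linspace(0, 5, 11), np.zeros(11)], axis=1)
        pts = base[None] + np.stack([10 * t, 3 * t], axis=1)[:, None, :]
        body = kin.TrackedBody(times=t, points=pts, frame_rate=240.0,
                               body_length=5.0)
        assert kin.compute_yaw(body) == pytest.approx(0.0, abs=1e-9)

    def test_imposed_heading_oscillation(self):
        spec = sy.movement_preset("swimming", head_yaw_deg=52.0, seed=4)
        body, _ = sy.make_tracked_movement(spec)
        cycles = [(k * 0.05, (k + 1) * 0.05) for k in range(2, 10)]
        yaw = np.nanmean(kin.compute_yaw(body, cycles))
        assert yaw == pytest.approx(104.0, rel=0.05)
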