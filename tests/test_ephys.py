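"""Burst statistics, rhythmicity, propagation and spike phases."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from tadstruggle import ephys
from tadstruggle import synthetic as sy


def _trace(samples, fs=10000.0, **kw):
    return ephys.RhythmTrace(samples=np.asarray(samples, float),
                             sampling_rate=fs, **kw)


class TestPreprocess:
    def test_rectification_is_absolute_value(self):
        rng = np.random.default_rng(0)
        x = -np.abs(rng.normal(size=4000)) - 1.0
        out = ephys.preprocess(_trace(x), iterations=0)
        assert np.array_equal(out.samples, np.abs(x))

    def test_rectification_idempotent(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=4000)
        once = ephys.preprocess(_trace(x), iterations=0)
        twice = ephys.preprocess(once, iterations=0)
        assert np.array_equal(once.samples, twice.samples)

    def test_impulse_response_is_iterated_boxcar(self):
        # 4 iterations of a width-w moving average == the boxcar
        # convolved with itself 4 times (mass 1, near-Gaussian)
        fs, w_ms = 10000.0, 2.5
        w = int(round(w_ms * 1e-3 * fs))
        x = np.zeros(2001)
        x[1000] = 1.0
        out = ephys.preprocess(_trace(x), smooth_window=w_ms).samples
        box = np.ones(w) / w
        expect = np.array([1.0])
        for _ in range(4):
            expect = np.convolve(expect, box)
        center = 1000
        half = (expect.size - 1) // 2
        assert np.allclose(out[center - half:center + half + 1], expect,
                           atol=1e-12)
        assert out.sum() == pytest.approx(1.0, abs=1e-12)

    def test_artifact_window_zeroed_elsewhere_untouched(self):
        x = np.ones(10000)
        out = ephys.preprocess(_trace(x, artifact_windows=((0.2, 0.3),)),
                               iterations=0)
        assert np.all(out.samples[2000:3000] == 0.0)
        assert np.all(out.samples[:2000] == 1.0)
        assert np.all(out.samples[3000:] == 1.0)

    def test_smoothing_preserves_mean(self):
        rng = np.random.default_rng(2)
        x = np.abs(rng.normal(size=20000))
        out = ephys.preprocess(_trace(x))
        assert out.samples.mean() == pytest.approx(np.abs(x).mean(),
                                                   rel=1e-12)

    def test_window_too_short_rejected(self):
        with pytest.raises(ValueError):
            ephys.preprocess(_trace(np.zeros(100), fs=5000.0),
                             smooth_window=0.2)


class TestTriggerEvents:
    def test_gaussian_noise_crossing_rate_matches_analytic(self):
        # i.i.d. Gaussian noise: an upward crossing of the level
        # mean + k*sd occurs at a pair (below, above); expected count is
        # n * Phi(k') * (1 - Phi(k')) with k' the level in true-sd units
        rng = np.random.default_rng(7)
        n, k = 400000, 3.0
        x = rng.normal(0.0, 5.0, size=n)
        tr = _trace(x)
        ev = ephys.trigger_events(tr, (0.0, n / 10000.0), k=k,
                                  refractory=0.0)
        kp = (ev.threshold / 5.0)
        p = stats.norm.cdf(kp) * stats.norm.sf(kp)
        expect = n * p
        assert abs(ev.event_times.size - expect) < 3 * np.sqrt(expect)

    def test_subthreshold_trace_gives_empty_train(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1.0, 30000)
        x[:20000] *= 5.0  # baseline much noisier than the rest
        ev = ephys.trigger_events(_trace(x), (0.0, 2.0), k=6.0)
        assert ev.event_times.size == 0

    def test_bursts_trigger_inside_not_between(self):
        spec = sy.TraceSpec(channels=(("left", 0.5),), duration=1.1,
                            cycle_period=300.0, burst_duration=60.0,
                            noise_sd=2.0, seed=9)
        traces, truth = sy.make_vr_traces(spec)
        rect = ephys.preprocess(traces[0], iterations=0)
        ev = ephys.trigger_events(rect, (0.0, 0.04), k=5.0)
        onsets = truth.burst_onsets[0]
        for onset in onsets:
            inside = (ev.event_times >= onset - 0.005) & (
                ev.event_times <= onset + 0.065)
            assert inside.sum() >= 1
        mid_gaps = onsets[:-1] + 0.1
        for g in mid_gaps:
            between = (ev.event_times > g) & (ev.event_times < g + 0.1)
            assert between.sum() == 0

    def test_empty_baseline_rejected(self):
        with pytest.raises(ValueError):
            ephys.trigger_events(_trace(np.ones(100)), (0.5, 0.6))

    def test_refractory_blocks_double_triggering(self):
        x = np.zeros(10000)
        x[5000:5005] = [10, 0, 10, 0, 10]  # re-crossings within 0.5 ms
        x[:1000] = np.random.default_rng(0).normal(0, 1.0, 1000)
        ev = ephys.trigger_events(_trace(x), (0.0, 0.1), k=5.0)
        assert ev.event_times.size == 1


class TestGroupBursts:
    def test_hand_enumerated_grouping(self):
        t = np.array([0, 5, 10, 250, 255, 260, 500, 505, 510]) / 1000.0
        ev = ephys.EventTrain(t, threshold=1.0, baseline_sd=0.2)
        bursts, rs = ephys.group_bursts(ev, max_gap=20.0)
        assert len(bursts) == 3
        assert all(b.duration == pytest.approx(10.0) for b in bursts)
        assert rs.cycle_period == pytest.approx(250.0)
        assert rs.frequency == pytest.approx(4.0)
        assert rs.duty_cycle == pytest.approx(0.04)

    def test_single_event_single_burst_no_period(self):
        ev = ephys.EventTrain(np.array([0.1]), threshold=1.0,
                              baseline_sd=0.2)
        bursts, rs = ephys.group_bursts(ev)
        assert len(bursts) == 1
        assert bursts[0].duration == 0.0
        assert np.isnan(rs.cycle_period)
        assert "single_burst_no_period" in rs.flags

    def test_struggling_train_duty_recovered(self, vr_pair):
        traces, truth = vr_pair
        ev = ephys.EventTrain(truth.event_times[0], threshold=1.0,
                              baseline_sd=0.1)
        _, rs = ephys.group_bursts(ev, max_gap=15.0)
        assert rs.cycle_period == pytest.approx(250.0, rel=0.10)
        # burst = events spanning the 77 ms window at 150 Hz
        assert rs.duty_cycle == pytest.approx(0.29, rel=0.10)


class TestRhythmicity:
    def test_perfectly_periodic_train_is_one(self):
        r = ephys.rhythmicity_index(np.arange(40) * 0.25)
        assert r.value == 1.0
        assert not r.flagged

    def test_monotone_interval_histogram_flagged_zero(self):
        # geometrically decaying interval counts: a strictly monotone
        # histogram has no interior trough, hence no rhythmicity
        counts = [64, 32, 16, 8, 4, 2, 1]
        iv = np.concatenate([np.full(c, (i + 0.5) * 0.005)
                             for i, c in enumerate(counts)])
        rng = np.random.default_rng(0)
        r = ephys.rhythmicity_index(np.cumsum(rng.permutation(iv)))
        assert r.value == 0.0
        assert r.flagged

    def test_poisson_trains_near_zero(self):
        vals = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            t = np.cumsum(rng.exponential(0.1, 300))
            vals.append(ephys.rhythmicity_index(t).value)
        assert np.mean(vals) < 0.15
        assert max(vals) < 0.35

    def test_bursty_train_with_empty_interior_is_one(self):
        t = np.concatenate([k * 0.25 + np.array([0.0, 0.005, 0.010])
                            for k in range(20)])
        r = ephys.rhythmicity_index(t, bin_width=5.0)
        assert r.value == 1.0

    def test_invariant_under_time_rescaling(self):
        t = np.concatenate([k * 0.25 + np.array([0, 0.006, 0.012, 0.018])
                            for k in range(30)])
        a = ephys.rhythmicity_index(t, bin_width=5.0)
        b = ephys.rhythmicity_index(2.0 * t, bin_width=10.0)
        assert a.value == pytest.approx(b.value, abs=1e-12)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_r_always_in_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(11, 200))
        t = np.cumsum(rng.gamma(rng.uniform(0.5, 5), 0.05, size=n))
        r = ephys.rhythmicity_index(t)
        assert 0.0 <= r.value <= 1.0

    def test_too_few_intervals_rejected(self):
        with pytest.raises(ValueError):
            ephys.rhythmicity_index(np.arange(5) * 0.1)


class TestXcorrPropagation:
    def test_constructed_delay_and_speed(self):
        rng = np.random.default_rng(4)
        fs = 10000.0
        base = np.convolve(rng.normal(size=40000),
                           np.exp(-np.arange(200) / 50.0), mode="same")
        base += 5 * np.sin(2 * np.pi * 4 * np.arange(40000) / fs)
        shift = 100  # 10 ms
        a = _trace(np.abs(base[shift:]), side="left", position=2.0)
        b = _trace(np.abs(base[:-shift]), side="left", position=1.5)
        out = ephys.xcorr_propagation(a, b)
        assert out.delay == pytest.approx(10.0, abs=0.5)
        assert out.speed == pytest.approx(50.0, rel=0.05)

    def test_identical_traces_synchronous(self):
        t = np.arange(40000) / 10000.0
        x = np.abs(np.sin(2 * np.pi * 4 * t))
        a = _trace(x, position=1.0)
        b = _trace(x.copy(), position=2.0)
        out = ephys.xcorr_propagation(a, b)
        assert out.synchronous

    def test_synthetic_pair_recovers_imposed_speed(self, vr_pair):
        traces, _ = vr_pair
        a = ephys.preprocess(traces[0])
        b = ephys.preprocess(traces[1])
        out = ephys.xcorr_propagation(a, b)
        assert out.speed == pytest.approx(53.8, rel=0.05)

    def test_antisymmetric_under_channel_swap(self, vr_pair):
        traces, _ = vr_pair
        a = ephys.preprocess(traces[0])
        b = ephys.preprocess(traces[1])
        fwd = ephys.xcorr_propagation(a, b)
        rev = ephys.xcorr_propagation(b, a)
        assert rev.delay == pytest.approx(-fwd.delay, abs=0.3)
        assert rev.speed == pytest.approx(fwd.speed, rel=0.05)

    def test_same_position_rejected(self):
        a = _trace(np.ones(10000), position=1.0)
        with pytest.raises(ValueError):
            ephys.xcorr_propagation(a, a)


class TestSpikePhases:
    def test_spike_at_onset_zero_distance(self):
        phi = ephys.phase_of_spikes(np.array([1.0]),
                                    np.array([1.0, 1.25, 1.5]))
        assert phi[0] == pytest.approx(0.0, abs=1e-12)

    def test_contralateral_boundary_wraps_to_plus_half(self):
        phi = ephys.phase_of_spikes(np.array([1.0]),
                                    np.array([1.0, 1.25, 1.5]),
                                    contralateral=True)
        assert phi[0] == pytest.approx(0.5, abs=1e-12)

    def test_calibration_term_at_reference_distance(self):
        # L = 1.65 mm, period 0.25 s: delay = 0.185 - 0.00225*0.25
        phi = ephys.phase_of_spikes(np.array([1.0]),
                                    np.array([1.0, 1.25, 1.5]),
                                    distance_l=1.65)
        assert phi[0] == pytest.approx(-(0.185 - 0.00225 * 0.25), abs=1e-9)

    def test_phases_always_in_half_open_interval(self):
        rng = np.random.default_rng(5)
        onsets = np.cumsum(rng.uniform(0.2, 0.3, 50))
        spikes = rng.uniform(onsets[0], onsets[-1], 300)
        phi = ephys.phase_of_spikes(spikes, onsets, distance_l=2.5,
                                    contralateral=True)
        assert np.all(phi > -0.5)
        assert np.all(phi <= 0.5)

    def test_non_positive_period_rejected(self):
        with pytest.raises(ValueError):
            ephys.phase_of_spikes(np.array([0.1]), np.array([1.0, 1.0]))


class TestRhythmicityGradient:
    def test_sporadic_caudal_bursting_lowers_rhythmicity(self):
        """Channels toward the tail, given increasingly sporadic bursting
        (dropout + onset jitter), show decreasing rhythmicity indices."""
        res = {0: [], 1: [], 2: []}
        for seed in range(10):
            spec = sy.TraceSpec(
                channels=(("left", 0.5), ("left", 2.0), ("left", 3.5)),
                dropout=(0.0, 0.3, 0.6), jitter=(0.01, 0.1, 0.22),
                noise_sd=4.0, event_rate_in_burst=400.0, duration=12.0,
                seed=seed)
            traces, _ = sy.make_vr_traces(spec)
            for i, tr in enumerate(traces):
                rect = ephys.preprocess(tr, iterations=0)
                ev = ephys.trigger_events(rect, (0.0, 0.18), k=4.5)
                res[i].append(ephys.rhythmicity_index(ev.event_times).value)
        means = [np.mean(res[i]) for i in range(3)]
        assert means[0] > means[1] > means[2]
        extremes = sum(1 for s in range(10) if res[0][s] > res[2][s])
        assert extremes >= 9
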