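"""Phase estimation, forward prediction and trigger safety."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import cardiogate as cg
from cardiogate.core import (AperiodicInputError, InsufficientHistoryError,
                             ParameterError)
from cardiogate.gating import PhaseFit

TWO_PI = 2 * math.pi


def brute_force_crossing(fit, target, now_ms, latency_ms, resolution_ms=0.01):
    """Independent oracle: scan the fitted phase line on a fine time grid for
    the first target crossing after now + latency."""
    horizon = 2.5 * TWO_PI / fit.slope_rad_per_ms
    t = now_ms + latency_ms + np.arange(resolution_ms, horizon, resolution_ms)
    cycle = np.floor((fit.slope_rad_per_ms * t + fit.intercept_rad - target)
                     / TWO_PI + 1e-12)
    jump = np.nonzero(cycle > cycle[0])[0]
    assert len(jump), "no crossing inside scan horizon"
    return t[jump[0]]


class TestEstimatePeriod:
    def test_recovers_period_within_half_frame(self, heart_video):
        video, _ = heart_video
        est = cg.estimate_period(video)
        assert abs(est - 400.0) <= (1000 / 30) / 2

    def test_recovers_fast_rate_at_higher_sampling(self):
        video, _ = cg.generate_heart_video(cg.HeartSimParams(
            period_ms=300.0, fps=60.0, n_frames=120))
        est = cg.estimate_period(video)
        assert abs(est - 300.0) <= (1000 / 60) / 2

    def test_identical_frames_are_aperiodic(self):
        frames = np.ones((40, 16, 16))
        video = cg.VideoSequence(frames, np.arange(40) * 33.3, 1.0, 30.0)
        with pytest.raises(AperiodicInputError):
            cg.estimate_period(video)

    def test_prefers_fundamental_over_harmonics(self):
        video, _ = cg.generate_heart_video(cg.HeartSimParams(
            n_frames=90, noise_sigma=0.05, seed=3))
        est = cg.estimate_period(video)
        assert abs(est - 400.0) <= (1000 / 30) / 2


class TestBuildReference:
    def test_integer_period_yields_that_many_frames(self, heart_video):
        video, _ = heart_video
        refs = cg.build_reference(video, 400.0, anchor_frame=0, target_phase=0.0)
        assert len(refs.ref_frames) == 12  # 400 ms at 30 fps

    def test_end_diastole_anchor_matches_truth_phase(self, heart_video):
        video, truth = heart_video
        refs = cg.build_reference(video, 400.0, 0, "end-diastole")
        anchored = truth.phase_per_frame[np.argmax(
            truth.area_per_frame_um2[:12])]
        quantum = TWO_PI / 12
        assert float(cg.circular_distance(anchored, 0.0)) <= quantum
        assert refs.target_phase == 0.0

    def test_constant_area_video_has_no_end_diastole(self):
        video, _ = cg.generate_heart_video(cg.HeartSimParams(ef_true_pct=0.0))
        with pytest.raises(ParameterError):
            cg.build_reference(video, 400.0, 0, "end-diastole")

    def test_period_longer_than_video_raises(self, heart_video):
        video, _ = heart_video
        with pytest.raises(ParameterError):
            cg.build_reference(video, 400.0, anchor_frame=len(video) - 2,
                               target_phase=0.0)


class TestEstimatePhase:
    def test_exact_reference_frame_returns_exact_phase(self, reference_set):
        noise_conf = cg.estimate_phase(
            np.random.default_rng(1).random(reference_set.ref_frames.shape[1:]),
            reference_set).confidence
        for j in (0, 3, 7):
            pe = cg.estimate_phase(reference_set.ref_frames[j], reference_set)
            assert pe.phase == reference_set.ref_phases[j]
            assert pe.score == pytest.approx(1.0)
            assert pe.confidence >= 0.5 > noise_conf  # above the trigger floor

    def test_noiseless_phase_error_below_one_quantum_everywhere(
            self, heart_video, reference_set):
        video, truth = heart_video
        quantum = TWO_PI / len(reference_set.ref_frames)
        estimates = cg.estimate_phases(video, reference_set)
        errors = [float(cg.circular_distance(pe.phase, truth.phase_per_frame[i]))
                  for i, pe in enumerate(estimates)]
        assert max(errors) <= quantum

    def test_pure_noise_frame_has_low_confidence(self, reference_set):
        rng = np.random.default_rng(0)
        shape = reference_set.ref_frames.shape[1:]
        confs = [cg.estimate_phase(rng.random(shape), reference_set).confidence
                 for _ in range(20)]
        assert max(confs) < 0.5  # below the trigger confidence floor


class TestUnwrapAndFit:
    @staticmethod
    def _history(phases, confidence=1.0):
        return [cg.PhaseEstimate(i, float(p % TWO_PI), 1.0, confidence)
                for i, p in enumerate(phases)]

    def test_exact_phases_recover_slope_to_machine_precision(self):
        t = np.arange(12) * 1000 / 30
        truth_slope = TWO_PI / 400
        fit = cg.unwrap_and_fit(self._history(truth_slope * t), t, window=12)
        assert fit.slope_rad_per_ms == pytest.approx(truth_slope, rel=1e-9)
        assert fit.residual_rad < 1e-9

    def test_constant_phase_yields_withheld_trigger(self):
        t = np.arange(8) * 33.3
        fit = cg.unwrap_and_fit(self._history(np.full(8, 1.0)), t)
        event = cg.predict_trigger(fit, target_phase=0.0, now_ms=t[-1])
        assert event.withheld and event.reason == "pause/asystole"

    def test_insufficient_history_raises(self):
        t = np.arange(8) * 33.3
        history = self._history(np.linspace(0, 3, 8), confidence=0.0)
        with pytest.raises(InsufficientHistoryError):
            cg.unwrap_and_fit(history, t)

    def test_noisy_slope_within_three_standard_errors(self):
        # Monte-Carlo: Gaussian phase noise of known sigma; the fitted slope
        # should land within 3 analytic standard errors of truth in >=95%
        # of seeded repeats.
        t = np.arange(8) * 1000 / 30
        truth_slope = TWO_PI / 400
        sigma = 0.05
        x = t - t.mean()
        se = sigma / math.sqrt(float(np.sum(x ** 2)))
        hits = 0
        n_seeds = 200
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            phases = truth_slope * t + rng.normal(0, sigma, len(t))
            fit = cg.unwrap_and_fit(self._history(phases), t)
            hits += abs(fit.slope_rad_per_ms - truth_slope) <= 3 * se
        assert hits / n_seeds >= 0.95


class TestPredictTrigger:
    def test_full_period_when_already_at_target(self):
        fit = PhaseFit(TWO_PI / 400, 0.0, 0.0, 8, 1000.0)
        event = cg.predict_trigger(fit, target_phase=0.0, now_ms=400.0)
        assert event.fire_time_ms == pytest.approx(800.0, abs=1e-9)
        assert event.predicted_period_ms == pytest.approx(400.0)

    def test_latency_subtracts_exactly(self):
        fit = PhaseFit(TWO_PI / 400, 0.3, 0.0, 8, 1000.0)
        base = cg.predict_trigger(fit, 1.0, now_ms=500.0, latency_ms=0.0)
        shifted = cg.predict_trigger(fit, 1.0, now_ms=500.0, latency_ms=5.0)
        assert shifted.fire_time_ms == pytest.approx(base.fire_time_ms - 5.0)

    @given(period=st.floats(200, 1000), intercept=st.floats(-10, 10),
           target=st.floats(0, TWO_PI), latency=st.floats(0, 20),
           extra=st.floats(0.1, 30))
    def test_latency_monotonically_advances_fire_time(self, period, intercept,
                                                      target, latency, extra):
        fit = PhaseFit(TWO_PI / period, intercept, 0.0, 8, 0.0)
        a = cg.predict_trigger(fit, target, now_ms=100.0, latency_ms=latency)
        b = cg.predict_trigger(fit, target, now_ms=100.0,
                               latency_ms=latency + extra)
        crossing_a = a.fire_time_ms + latency
        crossing_b = b.fire_time_ms + latency + extra
        assert crossing_b >= crossing_a - 1e-6
        if 100.0 + latency + extra < crossing_a:
            # crossing still reachable: fire time decreases by exactly the
            # added latency
            assert b.fire_time_ms == pytest.approx(a.fire_time_ms - extra,
                                                   abs=1e-6)

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            period = rng.uniform(250, 700)
            fit = PhaseFit(TWO_PI / period, rng.uniform(-20, 20),
                           rng.uniform(0, 0.2), 8, 0.0)
            target = rng.uniform(0, TWO_PI)
            now = rng.uniform(0, 5000)
            latency = rng.uniform(0, 10)
            event = cg.predict_trigger(fit, target, now, latency)
            scanned = brute_force_crossing(fit, target, now, latency)
            assert abs((event.fire_time_ms + latency) - scanned) <= 0.02


class TestGateStream:
    def test_noiseless_triggers_hit_true_crossings(self, heart_video,
                                                   reference_set):
        video, truth = heart_video
        events = cg.gate_stream(video, reference_set,
                                cg.GateConfig(n_pulses=100, refractory_ms=0.0))
        fired = [e for e in events if not e.withheld]
        assert len(fired) >= 8
        for e in fired:
            nearest = np.min(np.abs(e.fire_time_ms - truth.target_phase_times_ms))
            assert nearest <= video.frame_interval_ms

    def test_multi_pulse_schedule_count_and_spacing(self):
        video, _ = cg.generate_heart_video(cg.HeartSimParams(n_frames=600))
        refs = cg.build_reference(video, cg.estimate_period(video), 0,
                                  "end-diastole")
        cfg = cg.GateConfig(n_pulses=5, refractory_ms=3000.0)
        fired = [e for e in cg.gate_stream(video, refs, cfg) if not e.withheld]
        assert len(fired) == 5
        gaps = np.diff([e.fire_time_ms for e in fired])
        assert (gaps >= 3000.0).all()

    def test_no_triggers_inside_pause(self):
        for seed in range(5):
            params = cg.HeartSimParams(
                n_frames=260, pause_onset_frame=90 + seed, noise_sigma=0.05,
                pause_duration_ms=2500.0, post_pause_period_ms=512.0, seed=seed)
            video, _ = cg.generate_heart_video(params)
            head = cg.VideoSequence(video.frames[:80], video.timestamps_ms[:80],
                                    video.pixel_size_um, video.fps)
            refs = cg.build_reference(video, cg.estimate_period(head), 0,
                                      "end-diastole")
            events = cg.gate_stream(video, refs,
                                    cg.GateConfig(n_pulses=100, refractory_ms=0.0))
            t_pause = (90 + seed) * 1000 / 30
            for e in events:
                if not e.withheld:
                    assert not (t_pause < e.fire_time_ms < t_pause + 2500.0)

    def test_identical_rerender_gives_identical_triggers(self):
        params = cg.HeartSimParams(noise_sigma=0.05, seed=5)
        v1, _ = cg.generate_heart_video(params)
        v2, _ = cg.generate_heart_video(params)
        refs = cg.build_reference(v1, cg.estimate_period(v1), 0, "end-diastole")
        cfg = cg.GateConfig(n_pulses=100, refractory_ms=0.0)
        e1 = cg.gate_stream(v1, refs, cfg)
        e2 = cg.gate_stream(v2, refs, cfg)
        assert [(e.fire_time_ms, e.withheld) for e in e1] == \
               [(e.fire_time_ms, e.withheld) for e in e2]


class TestPulsePower:
    @pytest.mark.parametrize("energy,duration,expected", [
        (0.9, 3.0, 300.0),   # the standard injury pulse
        (1.0, 1.0, 1000.0),
        (0.9, 9.0, 100.0),
    ])
    def test_power_is_energy_over_duration(self, energy, duration, expected):
        spec = cg.LaserPulseSpec(energy_mJ=energy, duration_ms=duration)
        assert cg.pulse_power(spec) == pytest.approx(expected)

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(ParameterError):
            cg.LaserPulseSpec(energy_mJ=0.9, duration_ms=0.0)

    def test_multi_pulse_needs_interval(self):
        with pytest.raises(ParameterError):
            cg.LaserPulseSpec(n_pulses=5)
        spec = cg.LaserPulseSpec(n_pulses=5, inter_pulse_interval_s=60.0)
        assert spec.n_pulses == 5
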