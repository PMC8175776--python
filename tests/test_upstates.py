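"""UP-state detector: envelope preprocessing, noise RMS, rule application."""

import math

import numpy as np
import pytest

from fxephys import (DetectionParams, RawRecording, UpStateSimParams,
                     detect_upstates, estimate_noise_rms, match_events,
                     preprocess_envelope, simulate_upstate_recording,
                     summarize_upstates)
from fxephys.upstates import EnvelopeTrace, UpStateEvent

from conftest import (brute_force_detect, events_to_sample_intervals,
                      random_envelope)

FAST = DetectionParams(lowpass_cutoff_hz=5.0)


def _env_from_values(values, rate_hz=1000.0, threshold=1.0):
    return EnvelopeTrace(env=np.asarray(values, dtype=float), rate_hz=rate_hz,
                         noise_rms=threshold / 4.0, threshold=threshold)


def _pulse_env(intervals_s, total_s=10.0, rate_hz=1000.0, high=2.0):
    env = np.zeros(int(total_s * rate_hz))
    for s, e in intervals_s:
        env[int(s * rate_hz):int(e * rate_hz)] = high
    return _env_from_values(env, rate_hz)


class TestPreprocess:
    def test_constant_signal_gives_zero_envelope(self):
        rec = RawRecording(samples=np.full(5000, 3.7), rate_hz=1000.0)
        env = preprocess_envelope(rec, FAST)
        assert np.allclose(env.env, 0.0)
        assert detect_upstates(env, FAST) == []

    def test_sign_flip_invariance(self, rng):
        x = rng.standard_normal(5000)
        a = preprocess_envelope(RawRecording(samples=x, rate_hz=1000.0), FAST)
        b = preprocess_envelope(RawRecording(samples=-x, rate_hz=1000.0), FAST)
        np.testing.assert_allclose(a.env, b.env, atol=1e-12)

    def test_envelope_ratio_tracks_gain(self):
        """Mean envelope inside vs outside events differs by ~(1 + gain)."""
        g = 3.0
        rec, gt = simulate_upstate_recording(
            UpStateSimParams(duration_s=300, gain=g, seed=11))
        env = preprocess_envelope(rec, FAST)
        inside = np.zeros(rec.n_samples, dtype=bool)
        for s, e in gt.events:
            # interior only: the 5 Hz envelope needs ~0.1 s to rise
            i0 = int((s + 0.15) * rec.rate_hz)
            i1 = int((e - 0.15) * rec.rate_hz)
            if i1 > i0:
                inside[i0:i1] = True
        outside = ~inside
        pad = int(1.0 * rec.rate_hz)
        for s, e in gt.events:
            outside[max(int(s * rec.rate_hz) - pad, 0):
                    int(e * rec.rate_hz) + pad] = False
        ratio = env.env[inside].mean() / env.env[outside].mean()
        assert ratio == pytest.approx(1 + g, rel=0.10)

    def test_cutoff_above_nyquist_rejected(self):
        rec = RawRecording(samples=np.ones(100), rate_hz=10.0)
        with pytest.raises(ValueError, match="Nyquist"):
            preprocess_envelope(rec, DetectionParams(lowpass_cutoff_hz=6.0))

    def test_short_recording_rejected(self):
        rec = RawRecording(samples=np.ones(100), rate_hz=100.0)  # 1 s
        with pytest.raises(ValueError, match="time constants"):
            preprocess_envelope(rec, FAST)  # needs >= 2 s at 5 Hz


class TestNoiseRms:
    def test_constant_envelope(self):
        assert estimate_noise_rms(np.full(1000, 2.5)) == pytest.approx(2.5)

    def test_rectified_gaussian(self, rng):
        """RMS of |N(0, sigma)| equals sigma (E[x^2] of the rectified
        variable is unchanged by rectification)."""
        est = estimate_noise_rms(np.abs(rng.standard_normal(1_000_000)))
        assert est == pytest.approx(1.0, rel=0.02)

    def test_contamination_excluded(self, rng):
        env = np.abs(rng.standard_normal(100_000))
        idx = rng.choice(env.size, size=env.size // 20, replace=False)
        env[idx] = 100.0
        assert estimate_noise_rms(env) == pytest.approx(1.0, rel=0.05)

    def test_zero_envelope(self):
        assert estimate_noise_rms(np.zeros(100)) == 0.0
        with pytest.raises(ValueError):
            estimate_noise_rms(np.array([]))


class TestDetectionRules:
    def test_all_below_threshold(self):
        env = _env_from_values(np.zeros(5000))
        assert detect_upstates(env) == []

    def test_merge_gap_rule(self):
        """Runs at [1.0,1.3) and [1.8,2.2): a 0.5 s gap merges into one
        1.2 s event; a 0.7 s gap leaves two events of 0.3 s and 0.4 s."""
        merged = detect_upstates(_pulse_env([(1.0, 1.3), (1.8, 2.2)]))
        assert len(merged) == 1
        assert merged[0].start_s == pytest.approx(1.0)
        assert merged[0].end_s == pytest.approx(2.2)
        assert merged[0].duration_s == pytest.approx(1.2)

        split = detect_upstates(_pulse_env([(1.0, 1.3), (2.0, 2.4)]))
        assert len(split) == 2
        assert split[0].duration_s == pytest.approx(0.3)
        assert split[1].duration_s == pytest.approx(0.4)

    def test_min_duration_rule(self):
        assert detect_upstates(_pulse_env([(1.0, 1.15)])) == []
        kept = detect_upstates(_pulse_env([(1.0, 1.25)]))
        assert len(kept) == 1
        assert kept[0].duration_s == pytest.approx(0.25)

    def test_boundary_events_dropped(self):
        env = _pulse_env([(0.0, 1.0), (4.0, 5.0), (9.5, 10.0)])
        events = detect_upstates(env)
        assert len(events) == 1
        assert events[0].start_s == pytest.approx(4.0)

    def test_oracle_equivalence(self, rng):
        """Detector output equals a literal brute-force rule application on
        200 random envelopes — exact boundary match."""
        params = DetectionParams()
        for _ in range(200):
            env = random_envelope(rng)
            got = events_to_sample_intervals(detect_upstates(env, params),
                                             env.rate_hz)
            ref = brute_force_detect(env.env, env.threshold, env.rate_hz)
            assert got == ref

    def test_structural_invariants(self, rng):
        params = DetectionParams()
        for _ in range(50):
            env = random_envelope(rng)
            events = detect_upstates(env, params)
            min_n = params.min_duration_samples(env.rate_hz)
            gap_n = params.merge_gap_samples(env.rate_hz)
            for e in events:
                assert e.duration_s * env.rate_hz >= min_n - 0.5
            for a, b in zip(events, events[1:]):
                assert (b.start_s - a.end_s) * env.rate_hz > gap_n

    def test_monotonicity_in_threshold(self, rng):
        """Lowering the threshold multiplier never decreases the total
        suprathreshold run time (before merging)."""
        env = random_envelope(rng)
        times = []
        for mult in (6.0, 4.0, 2.0):
            thr = mult * env.noise_rms
            times.append(int(np.sum(env.env > thr)))
        assert times == sorted(times)


class TestInvariances:
    def _detect(self, samples, rate=1000.0):
        rec = RawRecording(samples=samples, rate_hz=rate)
        env = preprocess_envelope(rec, FAST)
        return events_to_sample_intervals(detect_upstates(env, FAST), rate)

    def test_scale_invariance(self):
        rec, _ = simulate_upstate_recording(
            UpStateSimParams(duration_s=60, rate_hz=1000.0, seed=21))
        base = self._detect(rec.samples)
        assert base  # non-trivial case
        for c in (0.01, 100.0):
            assert self._detect(rec.samples * c) == base

    def test_offset_invariance(self):
        rec, _ = simulate_upstate_recording(
            UpStateSimParams(duration_s=60, rate_hz=1000.0, seed=22))
        base = self._detect(rec.samples)
        assert self._detect(rec.samples + 123.4) == base


class TestSummarize:
    def test_empty(self):
        s = summarize_upstates([], 600.0)
        assert s.n_events == 0
        assert s.freq_per_min == 0.0
        assert math.isnan(s.mean_duration_s)
        assert math.isnan(s.mean_amplitude)

    def test_arithmetic(self):
        events = [UpStateEvent(10.0, 11.0, 2.0), UpStateEvent(20.0, 22.0, 4.0)]
        s = summarize_upstates(events, 600.0)
        assert s.n_events == 2
        assert s.mean_duration_s == pytest.approx(1.5)
        assert s.mean_amplitude == pytest.approx(3.0)
        assert s.freq_per_min == pytest.approx(0.2)

    def test_parameter_recovery_at_default_gain(self):
        """With the default strong-event gain, the detector recovers the
        generative events nearly perfectly and the mean duration within 15%."""
        rec, gt = simulate_upstate_recording(UpStateSimParams(seed=31))
        env = preprocess_envelope(rec, FAST)
        events = detect_upstates(env, FAST)
        sens, prec = match_events(events, gt.events)
        assert sens >= 0.9
        assert prec >= 0.9
        s = summarize_upstates(events, rec.duration_s)
        true_mean = np.mean([e - s0 for s0, e in gt.events])
        assert s.mean_duration_s == pytest.approx(true_mean, rel=0.15)
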