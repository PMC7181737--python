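import numpy as np
import pytest

import strokekin as sk
from strokekin.mirror_metrics import (
    JitterEvents,
    RegisteredPair,
    detect_jitter,
    jitter_frequencies,
    peak_jitter_frequency,
    phase_improvement,
    tracking_error_dT,
    tracking_error_dV,
    tracking_error_dX,
    zero_crossings,
)
from strokekin.preprocess import KinematicSeries, differentiate


def series_1d(t, x):
    return differentiate(KinematicSeries(t=t, x=np.asarray(x, float), y=np.zeros_like(t)))


class TestZeroCrossings:
    def test_subsample_interpolation(self):
        t = np.arange(5, dtype=float)
        y = np.array([-1.0, -0.5, 0.5, 1.0, 2.0])
        (c,) = zero_crossings(t, y)
        assert c == pytest.approx(1.5)

    def test_touching_zero_without_sign_change_is_not_a_crossing(self):
        t = np.arange(6, dtype=float)
        y = np.array([1.0, 0.5, 0.0, 0.0, 0.5, 1.0])
        assert zero_crossings(t, y).size == 0

    def test_zero_run_with_flip_counts_once(self):
        t = np.arange(6, dtype=float)
        y = np.array([1.0, 0.5, 0.0, 0.0, -0.5, -1.0])
        assert zero_crossings(t, y).size == 1


class TestDetectJitter:
    def test_perfect_tracking_retains_nothing(self, slow_program, tracking_recipe):
        stim = sk.generate_stimulus(slow_program)
        raw, _ = sk.generate_follower(stim, sk.MirrorTrialPlan(program=slow_program))
        fol, st = tracking_recipe(raw, stim)
        ev = detect_jitter(fol, st)
        assert ev.n_events == 0
        assert ev.excluded_stimulus_matches > 0

    def test_poisson_corrections_recovered(self, slow_program, tracking_recipe):
        plan = sk.MirrorTrialPlan(program=slow_program, correction_rate=0.3, seed=5,
                                  correction_duration=0.25)
        stim = sk.generate_stimulus(slow_program)
        raw, truth = sk.generate_follower(stim, plan)
        fol, st = tracking_recipe(raw, stim)
        ev = detect_jitter(fol, st)
        injected = np.array(truth.injected_correction_times)
        assert injected.size > 0
        # every injected correction has a retained event nearby
        dist = np.min(np.abs(ev.event_times[:, None] - injected[None, :]), axis=0)
        assert np.all(dist < 0.2)

    def test_refractory_keeps_earlier_event(self):
        t = np.arange(0, 10, 0.01)
        # acceleration with sign flips at 2.0 and 2.1 s (0.1 s apart), then 5.0
        a = np.ones_like(t)
        a[(t >= 2.0) & (t < 2.1)] = -1.0
        a[t >= 5.0] = -1.0
        part = KinematicSeries(t=t, x=np.zeros_like(t), y=np.zeros_like(t))
        part.ax = a
        stim = KinematicSeries(t=t, x=np.zeros_like(t), y=np.zeros_like(t))
        stim.ax = np.ones_like(t)  # no stimulus crossings
        ev = detect_jitter(part, stim)
        assert ev.excluded_refractory == 1
        assert np.all(np.abs(ev.event_times - np.array([2.0, 5.0])) < 0.02)

    def test_retention_monotone_in_windows(self, slow_program, tracking_recipe):
        plan = sk.MirrorTrialPlan(program=slow_program, correction_wave_hz=0.8, seed=2)
        stim = sk.generate_stimulus(slow_program)
        raw, _ = sk.generate_follower(stim, plan)
        fol, st = tracking_recipe(raw, stim)
        n_by_sep = [detect_jitter(fol, st, min_sep=m).n_events for m in (0.2, 0.4, 0.8)]
        assert all(a >= b for a, b in zip(n_by_sep, n_by_sep[1:]))
        n_by_win = [detect_jitter(fol, st, stim_match_window=w).n_events
                    for w in (0.02, 0.05, 0.15)]
        assert all(a >= b for a, b in zip(n_by_win, n_by_win[1:]))


class TestJitterFrequencies:
    def test_half_reciprocal_rule(self):
        ev = JitterEvents(np.array([1.0, 2.0, 4.0]), 0, 0)
        np.testing.assert_allclose(jitter_frequencies(ev), [0.5, 0.25])

    def test_single_event_gives_empty(self):
        assert jitter_frequencies(JitterEvents(np.array([1.0]), 0, 0)).size == 0

    def test_refractory_bounds_frequencies_below_2_5(self):
        ev = JitterEvents(np.array([0.0, 0.201, 0.403]), 0, 0)
        assert np.all(jitter_frequencies(ev) < 2.5)

    def test_invalid_gap_rejected(self):
        with pytest.raises(ValueError, match="refractory"):
            JitterEvents(np.array([0.0, 0.1]), 0, 0)


class TestPeakJitterFrequency:
    def test_degenerate_sample(self):
        s = peak_jitter_frequency(np.full(10, 0.5))
        assert s.peak_frequency == pytest.approx(0.5)

    def test_bimodal_matches_dense_grid_oracle(self):
        rng = np.random.default_rng(8)
        f = np.concatenate([rng.normal(0.4, 0.02, 100), rng.normal(1.0, 0.02, 20)])
        summary = peak_jitter_frequency(f)
        assert abs(summary.peak_frequency - 0.4) < 0.05
        # independent oracle: explicit Gaussian-mixture density at the same bandwidth
        bw = summary.bandwidth_used
        grid = np.linspace(0, 1.5, 20001)
        dens = np.exp(-0.5 * ((grid[:, None] - f[None, :]) / bw) ** 2).sum(axis=1)
        assert abs(summary.peak_frequency - grid[np.argmax(dens)]) < 0.01

    def test_invariant_to_sample_duplication(self):
        rng = np.random.default_rng(9)
        f = rng.normal(0.6, 0.05, 60)
        a = peak_jitter_frequency(f, bandwidth=0.05).peak_frequency
        b = peak_jitter_frequency(np.concatenate([f, f]), bandwidth=0.05).peak_frequency
        assert abs(a - b) < 1e-6

    def test_too_few_events_advises_pooling(self):
        with pytest.raises(ValueError, match="pool"):
            peak_jitter_frequency(np.array([0.5, 0.6]))


class TestTrackingErrors:
    def _pair(self, x1, x2, v1=None, v2=None, x_c=0.0):
        n = len(x1)
        t = np.arange(n) / 100.0
        z = np.zeros(n)
        return RegisteredPair(
            t=t, x1=np.asarray(x1, float), x2=np.asarray(x2, float),
            v1=z if v1 is None else np.asarray(v1, float),
            v2=z if v2 is None else np.asarray(v2, float), x_c=x_c,
        )

    def test_identical_signals_zero_error(self):
        x = np.sin(np.arange(100) / 10.0) + 2.0
        v = np.cos(np.arange(100) / 10.0) + 2.0
        pair = self._pair(x, x, v, v)
        assert tracking_error_dX(pair) == 0.0
        assert tracking_error_dV(pair) == 0.0

    def test_dx_single_sample_hand_value(self):
        pair = self._pair([2.0], [1.0], x_c=0.0)
        assert tracking_error_dX(pair) == pytest.approx(2.0 / 3.0)

    def test_dx_symmetric_in_players(self):
        rng = np.random.default_rng(1)
        a, b = rng.uniform(1, 5, 50), rng.uniform(1, 5, 50)
        assert tracking_error_dX(self._pair(a, b)) == pytest.approx(
            tracking_error_dX(self._pair(b, a))
        )

    def test_dv_single_sample_hand_value(self):
        pair = self._pair([0.0], [0.0], v1=[3.0], v2=[1.0])
        assert tracking_error_dV(pair) == pytest.approx(1.0)

    def test_dv_cancelling_velocities_rejected(self):
        v = np.linspace(2, 5, 20)
        pair = self._pair(np.zeros(20), np.zeros(20), v, -v)
        with pytest.raises(ValueError, match="floor"):
            tracking_error_dV(pair)

    def test_dt_identical_series_zero(self):
        t = np.arange(0, 10, 0.01)
        s = series_1d(t, 50 * np.sin(2 * np.pi * 0.5 * t))
        assert tracking_error_dT(s, s) == pytest.approx(0.0, abs=1e-9)

    def test_dt_recovers_uniform_lag(self):
        t = np.arange(0, 20, 0.01)
        a = series_1d(t, 50 * np.sin(2 * np.pi * 0.5 * t))
        b = series_1d(t, 50 * np.sin(2 * np.pi * 0.5 * (t - 0.2)))
        assert tracking_error_dT(b, a) == pytest.approx(0.2, abs=0.01)

    def test_dt_ignores_surplus_distant_events(self):
        t = np.arange(0, 20, 0.01)
        stim = series_1d(t, 50 * np.sin(2 * np.pi * 0.25 * t))
        base = 50 * np.sin(2 * np.pi * 0.25 * (t - 0.1))
        # add a fast wiggle confined between stimulus reversals
        wiggle = 3.0 * np.sin(2 * np.pi * 4 * t) * ((t > 2.4) & (t < 2.6))
        part = series_1d(t, base + wiggle)
        clean = tracking_error_dT(series_1d(t, base), stim)
        noisy = tracking_error_dT(part, stim)
        assert abs(noisy - clean) < 0.02


class TestPhaseImprovement:
    def test_reported_improvement_pattern(self):
        # the slow-tracking reduction reported for the treated group at
        # 0.375 Hz: 0.836 -> 0.461 is an improvement of 0.375 Hz
        out = phase_improvement({0.375: 0.836}, {0.375: 0.461})
        assert out[0.375] == pytest.approx(0.375)

    def test_zero_and_negative_improvement(self):
        assert phase_improvement({0.25: 0.6}, {0.25: 0.6})[0.25] == 0.0
        assert phase_improvement({0.25: 0.5}, {0.25: 0.7})[0.25] == pytest.approx(-0.2)

    def test_key_mismatch_rejected(self):
        with pytest.raises(ValueError, match="keys"):
            phase_improvement({0.25: 0.5}, {0.375: 0.4})


def test_identity_follower_end_to_end(slow_program, tracking_recipe):
    """A follower identical to the stimulus: no jitter, near-zero errors."""
    stim = sk.generate_stimulus(slow_program)
    raw, _ = sk.generate_follower(stim, sk.MirrorTrialPlan(program=slow_program))
    fol, st = tracking_recipe(raw, stim)
    assert detect_jitter(fol, st).n_events == 0
    pair = RegisteredPair.from_series(fol, st, x_c=slow_program.center_x)
    assert tracking_error_dX(pair) < 0.01
    assert tracking_error_dV(pair) < 0.01
    assert tracking_error_dT(fol, st) < 0.01
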