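import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import strokekin as sk
from strokekin.coarticulation import (
    PeakTroughProfile,
    complete_profile,
    coarticulation_score,
    count_velocity_peaks,
    find_extrema,
    normalize_scores,
    register_trials,
)
from strokekin.preprocess import KinematicSeries
from strokekin.segmentation import MovementSegment


def profile_from(peaks, troughs, n_detected=None):
    """Build a completed profile directly from (time, height) pairs."""
    pt = np.array([p[0] for p in peaks], float)
    ph = np.array([p[1] for p in peaks], float)
    tt = np.array([t[0] for t in troughs], float)
    th = np.array([t[1] for t in troughs], float)
    return PeakTroughProfile(
        peak_times=pt, peak_heights=ph, trough_times=tt, trough_heights=th,
        n_detected_peaks=len(peaks) if n_detected is None else n_detected,
    )


def series_from_speed(t, v):
    """Wrap a speed profile (x is its running integral) with a full segment."""
    s = KinematicSeries(t=t, x=np.cumsum(v) * (t[1] - t[0]), y=np.zeros_like(t))
    s.v_tan = np.asarray(v, float)
    s.pressure = np.ones_like(t)
    seg = MovementSegment(
        onset_t=float(t[0]), offset_t=float(t[-1]), onset_idx=0,
        offset_idx=len(t) - 1, peak_vtan=float(np.max(v)),
    )
    return s, seg


def gaussian_bells(t, centers, heights, width=0.18):
    return sum(h * np.exp(-((t - c) ** 2) / (2 * width**2))
               for c, h in zip(centers, heights))


class TestFindExtrema:
    def test_four_separated_bells(self):
        t = np.arange(0, 4.0, 0.005)
        v = gaussian_bells(t, [0.5, 1.5, 2.5, 3.5], [100, 90, 95, 85], width=0.15)
        s, seg = series_from_speed(t, v)
        prof = find_extrema(s, seg)
        assert prof.n_detected_peaks == 4
        assert prof.trough_times.size == 3
        assert np.all(prof.trough_heights < 1.0)  # essentially full stops

    def test_merged_bells_detected_as_one_peak(self):
        t = np.arange(0, 2.0, 0.005)
        v = gaussian_bells(t, [0.8, 1.1], [100, 70])
        s, seg = series_from_speed(t, v)
        prof = find_extrema(s, seg)
        assert prof.n_detected_peaks == 1

    def test_monotone_ramp_has_no_interior_peak(self):
        t = np.arange(0, 1.0, 0.005)
        s, seg = series_from_speed(t, 100 * t)
        with pytest.raises(ValueError, match="no interior"):
            find_extrema(s, seg)

    def test_agrees_with_brute_force_scan_when_well_separated(self):
        """Independent oracle: plain 3-point local-extrema scan, no prominence."""
        t = np.arange(0, 4.0, 0.02)  # <= 200 samples
        v = gaussian_bells(t, [0.5, 1.5, 2.5, 3.5], [100, 90, 95, 85], width=0.15)
        s, seg = series_from_speed(t, v)
        prof = find_extrema(s, seg)
        brute = [i for i in range(1, len(v) - 1) if v[i] > v[i - 1] and v[i] > v[i + 1]]
        assert prof.n_detected_peaks == len(brute)
        np.testing.assert_allclose(prof.peak_times, t[brute], atol=0.021)


class TestCompleteProfile:
    def test_complete_profile_is_identity_on_four_peaks(self):
        t = np.arange(0, 4.0, 0.005)
        v = gaussian_bells(t, [0.5, 1.5, 2.5, 3.5], [100, 90, 95, 85], width=0.15)
        s, seg = series_from_speed(t, v)
        prof = find_extrema(s, seg)
        out = complete_profile(prof)
        assert out is prof
        assert not out.substituted_peaks.any()

    def test_three_peak_substitution_equal_heights(self):
        t = np.arange(0, 4.0, 0.005)
        # first two bells merged into one peak with a shoulder
        v = gaussian_bells(t, [0.6, 0.95, 2.0, 3.0], [100, 70, 90, 95])
        s, seg = series_from_speed(t, v)
        prof = find_extrema(s, seg)
        assert prof.n_detected_peaks == 3
        out = complete_profile(prof)
        assert out.n_peaks == 4 and out.trough_times.size == 3
        (sub_peak,) = np.nonzero(out.substituted_peaks)
        (sub_trough,) = np.nonzero(out.substituted_troughs)
        assert out.peak_heights[sub_peak[0]] == out.trough_heights[sub_trough[0]]
        assert out.n_detected_peaks == 3

    def test_two_peak_double_substitution(self):
        t = np.arange(0, 4.0, 0.005)
        # both the B and D merges: dominant second bell in the second pair
        # keeps its shoulder on the side of the expected via-point
        v = gaussian_bells(t, [0.6, 0.95, 2.45, 2.8], [100, 70, 60, 95])
        s, seg = series_from_speed(t, v)
        prof = find_extrema(s, seg)
        assert prof.n_detected_peaks == 2
        out = complete_profile(prof)
        assert out.n_peaks == 4
        assert out.substituted_peaks.sum() == 2
        for jp, jt in zip(np.nonzero(out.substituted_peaks)[0],
                          np.nonzero(out.substituted_troughs)[0]):
            assert out.peak_heights[jp] == out.trough_heights[jt]

    def test_single_peak_cannot_be_completed(self):
        t = np.arange(0, 2.0, 0.005)
        v = gaussian_bells(t, [1.0], [100])
        s, seg = series_from_speed(t, v)
        prof = find_extrema(s, seg)
        with pytest.raises(ValueError, match="2 or 3"):
            complete_profile(prof)


class TestScore:
    @pytest.mark.parametrize(
        "peak_heights, trough_heights, expected",
        [
            ((10, 10, 10, 10), (0, 7, 0), 0.0),       # full stops at scored troughs
            ((10, 10, 10, 10), (10, 10, 10), 100.0),  # no dips at all
            ((20, 10, 20, 10), (5, 2, 10), 50.0),     # mean(5,10)/mean(15)*100
        ],
    )
    def test_hand_computed_scores(self, peak_heights, trough_heights, expected):
        peaks = [(i, h) for i, h in zip((0.0, 1.0, 2.0, 3.0), peak_heights)]
        troughs = [(i + 0.5, h) for i, h in zip((0.0, 1.0, 2.0), trough_heights)]
        res = coarticulation_score(profile_from(peaks, troughs))
        assert res.score == pytest.approx(expected)

    def test_requires_completed_profile(self):
        prof = profile_from([(0, 10), (1, 10), (2, 10)], [(0.5, 2), (1.5, 2)])
        with pytest.raises(ValueError, match="4 peaks"):
            coarticulation_score(prof)

    def test_zero_mean_peak_errors(self):
        prof = profile_from(
            [(0, 0.0), (1, 0.0), (2, 0.0), (3, 0.0)],
            [(0.5, 0.0), (1.5, 0.0), (2.5, 0.0)],
        )
        with pytest.raises(ValueError, match="zero"):
            coarticulation_score(prof)

    def test_scale_invariance(self):
        base = profile_from(
            [(0, 20), (1, 15), (2, 25), (3, 18)], [(0.5, 4), (1.5, 9), (2.5, 7)]
        )
        scaled = profile_from(
            [(0, 60), (1, 45), (2, 75), (3, 54)], [(0.5, 12), (1.5, 27), (2.5, 21)]
        )
        assert coarticulation_score(base).score == pytest.approx(
            coarticulation_score(scaled).score
        )

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(st.floats(1.0, 100.0), min_size=4, max_size=4),
           st.lists(st.floats(0.0, 1.0), min_size=3, max_size=3))
    def test_score_bounded_for_valid_profiles(self, peaks, trough_fracs):
        """Any alternating profile with troughs below adjacent peaks scores 0-100."""
        troughs = [f * min(peaks[i], peaks[i + 1]) for i, f in enumerate(trough_fracs)]
        prof = profile_from(
            [(float(i), h) for i, h in enumerate(peaks)],
            [(i + 0.5, h) for i, h in enumerate(troughs)],
        )
        res = coarticulation_score(prof)
        assert 0.0 <= res.score <= 100.0


class TestPeakCountAndNormalization:
    def test_peak_count_reflects_detection_not_substitution(self):
        t = np.arange(0, 4.0, 0.005)
        v = gaussian_bells(t, [0.6, 0.95, 2.0, 3.0], [100, 70, 90, 95])
        s, seg = series_from_speed(t, v)
        prof = find_extrema(s, seg)
        assert count_velocity_peaks(prof) == 3
        assert count_velocity_peaks(complete_profile(prof)) == 3

    def test_normalize_subtracts_without_dividing(self):
        np.testing.assert_allclose(normalize_scores([30.0, 45.0], 15.0), [15.0, 30.0])
        np.testing.assert_allclose(normalize_scores([10.0], 15.0), [-5.0])
        with pytest.raises(ValueError, match="baseline"):
            normalize_scores([1.0], None)


class TestRegistration:
    def _trial(self, duration):
        t = np.arange(0, duration, duration / 400)
        v = 100 * np.sin(np.pi * t / duration) ** 2
        return series_from_speed(t, v)

    def test_mean_of_identical_trials_is_any_member(self):
        trials = [self._trial(2.0) for _ in range(3)]
        reg = register_trials(trials, n_grid=101)
        np.testing.assert_allclose(reg.mean_v_tan, reg.v_tan[0])

    def test_time_scale_invariance(self):
        reg = register_trials([self._trial(1.0), self._trial(3.0)], n_grid=101)
        np.testing.assert_allclose(reg.v_tan[0], reg.v_tan[1], rtol=1e-6, atol=1e-6)

    def test_mirrored_pair_averages_symmetric(self):
        t = np.arange(0, 2.0, 0.005)
        v = gaussian_bells(t, [0.5], [100]) + gaussian_bells(t, [1.2], [50])
        a = series_from_speed(t, v)
        b = series_from_speed(t, v[::-1].copy())
        reg = register_trials([a, b], n_grid=201)
        np.testing.assert_allclose(reg.mean_v_tan, reg.mean_v_tan[::-1], atol=1e-6)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            register_trials([])


def test_score_monotone_in_generator_overlap():
    """More stroke blending at B and D never lowers the score (clean trials)."""
    scores = []
    for ov in (0.0, 0.1, 0.2, 0.3, 0.4, 0.5):
        raw, _ = sk.generate_target_trial(sk.TargetTrialPlan(overlap=(ov, 0.0, ov)))
        series = sk.smooth_with_splines(raw)
        seg = sk.detect_bounds(series)
        prof = complete_profile(find_extrema(series, seg))
        scores.append(coarticulation_score(prof).score)
    assert all(b >= a for a, b in zip(scores, scores[1:]))
    assert scores[-1] > scores[0] + 50  # strongly responsive, not flat
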