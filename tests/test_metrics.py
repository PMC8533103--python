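"""Rate, interval, Poincare, and cross-correlation endpoint computations."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cardiovid import (
    BeatSeries,
    CardiacReport,
    ChamberLabel,
    InsufficientBeatsError,
    IntervalSeries,
    build_report,
    chamber_intervals,
    compute_bpm,
    cross_chamber_intervals,
    cross_correlation,
    poincare,
    rescale_intervals,
    round_half_up,
)


class TestComputeBpm:
    def test_regular_troughs_at_200fps(self):
        assert compute_bpm([0, 80, 160, 240], 0.005) == pytest.approx(150.0)

    def test_single_interval(self):
        assert compute_bpm([0, 100], 0.005) == pytest.approx(120.0)

    def test_matches_brute_force_oracle_on_random_trough_sets(self, rng):
        for _ in range(50):
            n = rng.integers(2, 40)
            frames = np.cumsum(rng.integers(10, 200, size=n))
            dur = float(rng.uniform(0.001, 0.05))
            # oracle: 60 over the plain mean of the consecutive intervals
            intervals = np.diff(frames) * dur
            oracle = 60.0 / intervals.mean()
            assert compute_bpm(frames, dur) == pytest.approx(oracle, abs=1e-9)

    def test_time_shift_invariance(self):
        a = compute_bpm([0, 80, 160], 0.005)
        b = compute_bpm([500, 580, 660], 0.005)
        assert a == pytest.approx(b, rel=1e-12)

    def test_fewer_than_two_troughs_rejected(self):
        with pytest.raises(InsufficientBeatsError):
            compute_bpm([17], 0.005)


class TestRoundHalfUp:
    @pytest.mark.parametrize(
        "x, expected", [(117.5, 118), (117.4, 117), (-0.5, 0), (2.5, 3), (-2.5, -2)]
    )
    def test_ties_go_toward_plus_infinity(self, x, expected):
        assert round_half_up(x) == expected

    @given(st.floats(min_value=-1e6, max_value=1e6))
    @settings(max_examples=100, deadline=None)
    def test_equals_floor_of_x_plus_half(self, x):
        assert round_half_up(x) == math.floor(x + 0.5)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            round_half_up(float("nan"))


class TestChamberIntervals:
    def test_consecutive_differences(self):
        beats = BeatSeries(ChamberLabel.ATRIUM, np.array([0.0, 0.4, 1.0]))
        out = chamber_intervals(beats)
        assert out.kind == "AA"
        assert out.values == pytest.approx([0.4, 0.6])

    def test_kind_follows_label(self):
        beats = BeatSeries(ChamberLabel.VENTRICLE, np.array([0.0, 0.5, 1.0]))
        assert chamber_intervals(beats).kind == "VV"

    def test_matches_generator_drawn_intervals(self):
        from cardiovid import SyntheticHeartSpec, generate_beat_times
        spec = SyntheticHeartSpec(beat_jitter_sd_s=0.02, pulse_width_s=0.1, seed=5)
        truth = generate_beat_times(spec)
        beats = BeatSeries(ChamberLabel.ATRIUM, truth.atrium_beat_times)
        assert chamber_intervals(beats).values == pytest.approx(truth.atrium_intervals)


class TestCrossChamberIntervals:
    def test_fixed_offset(self):
        a = BeatSeries(ChamberLabel.ATRIUM, np.array([0.0, 0.5, 1.0]))
        v = BeatSeries(ChamberLabel.VENTRICLE, np.array([0.12, 0.62, 1.12]))
        av, va = cross_chamber_intervals(a, v)
        assert av.values == pytest.approx([0.12, 0.12, 0.12])
        assert va.values == pytest.approx([0.38, 0.38])

    def test_empty_partner_warns_and_returns_empty(self):
        a = BeatSeries(ChamberLabel.ATRIUM, np.array([0.0]))
        v = BeatSeries(ChamberLabel.VENTRICLE, np.array([]))
        with pytest.warns(UserWarning):
            av, va = cross_chamber_intervals(a, v)
        assert len(av.values) == 0
        assert len(va.values) == 0

    def test_unpaired_trailing_beats_dropped(self):
        a = BeatSeries(ChamberLabel.ATRIUM, np.array([0.0, 1.0, 2.0]))
        v = BeatSeries(ChamberLabel.VENTRICLE, np.array([0.1, 1.1]))
        av, _ = cross_chamber_intervals(a, v)
        assert av.values == pytest.approx([0.1, 0.1])  # last atrium beat unpaired


class TestPoincare:
    def test_perfect_regularity_gives_zero(self):
        stats = poincare(IntervalSeries("AA", np.full(10, 0.5)))
        assert stats.sd1 == 0.0
        assert stats.sd2 == 0.0

    def test_alternating_intervals(self):
        vals = np.tile([0.4, 0.6], 10)
        stats = poincare(IntervalSeries("AA", vals))
        # diffs alternate +/-0.2 -> sd1 ~ 0.2/sqrt(2); sums constant -> sd2 = 0
        assert stats.sd1 == pytest.approx(0.2 / np.sqrt(2), rel=0.01)
        assert stats.sd2 == pytest.approx(0.0, abs=1e-12)

    def test_iid_time_jitter_gives_sd1_sigma_sqrt3(self, rng):
        # brute-force oracle on true beat times: t_k = k*T + eps_k
        sigma = 0.01
        eps = rng.normal(0, sigma, size=5000)
        times = np.arange(5000) * 0.4 + eps
        intervals = np.diff(np.sort(times))
        stats = poincare(IntervalSeries("AA", intervals))
        assert stats.sd1 == pytest.approx(sigma * np.sqrt(3), rel=0.05)

    def test_scale_equivariance(self, rng):
        vals = rng.uniform(0.3, 0.5, size=50)
        base = poincare(IntervalSeries("AA", vals))
        scaled = poincare(IntervalSeries("AA", 3.0 * vals))
        assert scaled.sd1 == pytest.approx(3 * base.sd1, rel=1e-9)
        assert scaled.sd2 == pytest.approx(3 * base.sd2, rel=1e-9)

    def test_too_few_intervals_rejected(self):
        with pytest.raises(InsufficientBeatsError):
            poincare(IntervalSeries("AA", np.array([0.5, 0.5])))


class TestCrossCorrelation:
    def test_self_correlation_is_one_at_zero_lag(self, rng):
        x = rng.normal(size=200)
        cc = cross_correlation(x, x, max_delay=10)
        assert cc.r[cc.delays == 0][0] == pytest.approx(1.0, abs=1e-12)
        assert cc.peak_lag == 0

    def test_negated_copy_gives_minus_one(self, rng):
        x = rng.normal(size=200)
        cc = cross_correlation(x, -x, max_delay=5)
        assert cc.r[cc.delays == 0][0] == pytest.approx(-1.0, abs=1e-12)

    @pytest.mark.parametrize("k", range(1, 11))
    def test_delayed_copy_lag_recovery(self, k, rng):
        x = rng.normal(size=400)
        y = np.zeros_like(x)
        y[k:] = x[:-k]  # y lags x by k samples
        cc = cross_correlation(x, y, max_delay=20)
        assert cc.peak_lag == k

    def test_bounded_on_random_pairs(self, rng):
        for _ in range(200):
            n = int(rng.integers(5, 60))
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            cc = cross_correlation(x, y, max_delay=n - 1)
            assert np.all(cc.r <= 1 + 1e-12)
            assert np.all(cc.r >= -1 - 1e-12)

    def test_swap_symmetry_under_negated_lag(self, rng):
        x, y = rng.normal(size=100), rng.normal(size=100)
        fwd = cross_correlation(x, y, max_delay=15)
        rev = cross_correlation(y, x, max_delay=15)
        assert fwd.r == pytest.approx(rev.r[::-1], abs=1e-12)

    def test_constant_series_rejected(self):
        with pytest.raises(ZeroDivisionError):
            cross_correlation(np.ones(10), np.arange(10.0), max_delay=2)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            cross_correlation(np.arange(10.0), np.arange(9.0), max_delay=2)


class TestRescaleIntervals:
    def test_slow_clock_intervals_multiplied(self):
        out = rescale_intervals(IntervalSeries("AA", np.array([0.4])), 6.6)
        assert out.values == pytest.approx([2.64])
        assert out.kind == "AA"

    def test_identity_factor(self):
        vals = np.array([0.5, 0.5])
        out = rescale_intervals(IntervalSeries("VV", vals), 1.0)
        assert out.values == pytest.approx(vals)

    def test_nonpositive_factor_rejected(self):
        with pytest.raises(ValueError):
            rescale_intervals(IntervalSeries("AA", np.array([0.5])), 0.0)

    def test_slow_motion_round_trip_consistency(self, regular_clip):
        """Intervals measured on the playback clock of a slow-motion
        re-render (200 fps footage re-timed to 30 fps), mapped back through
        the 6.6 slowdown factor, match the 200 fps-clock intervals within
        one playback frame duration."""
        from cardiovid import (
            BoundingBox, ChamberLabel, VideoClip, bandpass, detect_peaks,
            extract_signal, normalize, slowdown_factor,
        )
        clip, _ = regular_clip
        box = BoundingBox(18, 38, 28, 20)

        def trough_frames(c, band):
            sig = extract_signal(c, box, ChamberLabel.ATRIUM)
            filt = bandpass(normalize(sig.values), c.fps, *band)
            return detect_peaks(filt.values, c.fps).minima_indices

        fast = np.diff(trough_frames(clip, (0.5, 5.0)) / clip.fps)
        # same frames, slower clock: a 6.6-fold slow-motion re-render
        slow_clip = VideoClip(frames=clip.frames, fps=30.0)
        factor = slowdown_factor(clip.fps, 30.0)
        assert factor == pytest.approx(6.6)
        slow = np.diff(trough_frames(slow_clip, (0.1, 2.0)) / slow_clip.fps) / factor
        n = min(len(fast), len(slow))
        assert np.max(np.abs(fast[:n] - slow[:n])) <= 1 / 30 + 1e-9


class TestReport:
    def _beats(self):
        a = BeatSeries(ChamberLabel.ATRIUM, np.arange(20) * 0.4)
        v = BeatSeries(ChamberLabel.VENTRICLE, np.arange(20) * 0.4 + 0.1)
        return a, v

    def test_build_report_aggregates_endpoints(self):
        a, v = self._beats()
        report = build_report(a, v)
        assert report.bpm["atrium"] == pytest.approx(150.0)
        assert report.bpm["ventricle"] == pytest.approx(150.0)
        assert report.interval_stats["AV"][0] == pytest.approx(0.1)
        assert report.interval_stats["VA"][0] == pytest.approx(0.3)
        assert report.poincare_stats["atrium"].sd1 == pytest.approx(0.0, abs=1e-12)

    def test_insufficient_beats_names_chamber(self):
        a = BeatSeries(ChamberLabel.ATRIUM, np.array([0.0]))
        v = BeatSeries(ChamberLabel.VENTRICLE, np.arange(5) * 0.4)
        with pytest.raises(InsufficientBeatsError, match="atrium"):
            build_report(a, v)

    def test_csv_round_trip(self, tmp_path):
        a, v = self._beats()
        report = build_report(a, v)
        path = tmp_path / "report.csv"
        report.to_csv(path)
        back = CardiacReport.from_csv(path)
        assert report.round_trip_equal(back)
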