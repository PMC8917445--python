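"""Speed/acceleration estimation and robust summary statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import fastkin as fk
from fastkin.kinematics import robust_extremum, smooth_track


def _track(x, y, dt=1.0 / 353.0, valid=None):
    n = len(x)
    return fk.Track(
        fish_id="t",
        dish_id="d",
        frames=np.arange(n),
        time_s=np.arange(n) * dt,
        x_mm=np.asarray(x, float),
        y_mm=np.asarray(y, float),
        valid=np.ones(n, bool) if valid is None else valid,
    )


class TestSmoothTrack:
    def test_linear_motion_derivative_exact(self):
        t = np.arange(50) * 0.01
        tr = _track(30.0 * t, np.zeros_like(t), dt=0.01)
        _, vel, _, valid, _ = smooth_track(tr)
        assert valid.all()
        np.testing.assert_allclose(vel[3:-3, 0], 30.0, rtol=1e-9)

    def test_quadratic_motion_second_derivative_exact(self):
        t = np.arange(50) * 0.01
        tr = _track(5.0 * t**2, np.zeros_like(t), dt=0.01)
        _, _, acc, _, _ = smooth_track(tr, order=2)
        np.testing.assert_allclose(acc[3:-3, 0], 10.0, rtol=1e-8)

    def test_noise_suppression_vs_finite_differences(self):
        rng = np.random.default_rng(0)
        dt = 1.0 / 353.0
        t = np.arange(400) * dt
        truth = 25.0
        x = truth * t + rng.normal(0, 0.1, len(t))
        tr = _track(x, np.zeros_like(t), dt=dt)
        _, vel, _, _, _ = smooth_track(tr, window=7, order=2)
        sg_rmse = np.sqrt(np.mean((vel[3:-3, 0] - truth) ** 2))
        fd = np.diff(x) / dt
        fd_rmse = np.sqrt(np.mean((fd - truth) ** 2))
        assert fd_rmse / sg_rmse >= 3.0

    def test_short_valid_runs_are_invalidated(self):
        valid = np.ones(30, bool)
        valid[5:25] = False  # leaves runs of 5 at both ends
        tr = _track(np.arange(30.0), np.zeros(30), valid=valid)
        _, _, _, out_valid, _ = smooth_track(tr, window=7)
        assert not out_valid.any()

    def test_window_must_be_odd_and_longer_than_order(self):
        tr = _track(np.arange(20.0), np.zeros(20))
        with pytest.raises(ValueError, match="odd"):
            smooth_track(tr, window=6)
        with pytest.raises(ValueError, match="order"):
            smooth_track(tr, window=7, order=7)


class TestSpeedProfile:
    def test_uniform_circular_motion_recovers_v_and_a(self, circle_track):
        p = fk.compute_speed_profile(circle_track)
        interior = slice(5, -5)
        assert np.abs(p.speed[interior] - 20.0).max() / 20.0 < 0.02
        assert np.abs(p.accel[interior] - 40.0).max() / 40.0 < 0.05

    @pytest.mark.parametrize("dt", [1 / 200, 1 / 353, 1 / 500])
    def test_circle_across_frame_rates(self, dt):
        t = np.arange(0.0, 1.0, dt)
        tr = _track(10 * np.cos(2 * t), 10 * np.sin(2 * t), dt=dt)
        p = fk.compute_speed_profile(tr)
        interior = slice(5, -5)
        assert np.abs(p.speed[interior] - 20.0).max() / 20.0 < 0.02
        assert np.abs(p.accel[interior] - 40.0).max() / 40.0 < 0.05

    def test_tangential_acceleration_zero_on_circle(self, circle_track):
        p = fk.compute_speed_profile(circle_track, accel_mode="tangential")
        assert np.abs(p.accel[5:-5]).max() < 1.0  # mm/s^2, vs 40 for vector

    def test_stationary_fish_zero_speed(self):
        tr = _track(np.full(30, 3.0), np.full(30, -2.0))
        p = fk.compute_speed_profile(tr)
        assert np.abs(p.speed).max() < 1e-9
        assert np.abs(p.accel).max() < 1e-6

    def test_pulse_peak_recovered_from_track(self):
        trials = fk.simulate_fast_start_trials(
            fk.FastStartSimParams(n_fish=10, trials_per_fish=1, seed=7)
        )
        for t in trials:
            if t.meta["n_reflections"]:
                continue
            p = fk.compute_speed_profile(t.track)
            rel = abs(p.speed.max() - t.meta["true_peak_speed"])
            assert rel / t.meta["true_peak_speed"] < 0.05

    def test_speed_integral_matches_path_length(self):
        trials = fk.simulate_fast_start_trials(
            fk.FastStartSimParams(n_fish=15, seed=3)
        )
        checked = 0
        for t in trials:
            if t.meta["n_reflections"]:
                continue
            rel = abs(t.meta["path_length_mm"] - t.meta["speed_integral_mm"])
            assert rel <= 1e-3 * t.meta["speed_integral_mm"] + 1e-12
            checked += 1
        assert checked > 10


class TestRobustExtremum:
    def test_one_to_hundred(self):
        assert robust_extremum(np.arange(1.0, 101.0), q=0.95) == pytest.approx(98.0)

    def test_all_equal_falls_back_to_maximum(self):
        assert robust_extremum(np.full(17, 3.5)) == 3.5

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            n = rng.integers(1, 400)
            vals = rng.gamma(2.0, 30.0, size=n)
            # independent oracle: sort, threshold at the interpolated
            # quantile, average the strictly-greater tail
            thr = np.quantile(np.sort(vals), 0.95, method="linear")
            tail = vals[vals > thr]
            expected = tail.mean() if tail.size else vals.max()
            assert robust_extremum(vals, 0.95) == pytest.approx(expected, rel=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            robust_extremum(np.array([]))

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(
        st.lists(st.floats(0.0, 1e4), min_size=1, max_size=300),
        st.floats(0.0, 0.99),
    )
    def test_bounded_by_mean_and_max(self, vals, q):
        vals = np.asarray(vals)
        r = robust_extremum(vals, q)
        assert vals.mean() - 1e-9 <= r <= vals.max() + 1e-9


class TestSummarize:
    def test_constant_profile_mean_equals_max(self):
        n = 100
        p = fk.SpeedProfile("f", np.arange(n) * 0.01, np.full(n, 12.0), np.zeros(n), np.ones(n, bool))
        s = fk.summarize_kinematics(p)
        assert s.v_mean == s.v_max == 12.0

    def test_robust_max_below_raw_spike(self):
        # continuous background speeds plus one extreme spike: the top-5%
        # tail averages the spike with ordinary values, damping it
        n = 200
        speed = np.linspace(0.0, 20.0, n)
        speed[50] = 500.0
        p = fk.SpeedProfile("f", np.arange(n) * 0.01, speed, np.zeros(n), np.ones(n, bool))
        s = fk.summarize_kinematics(p)
        assert s.v_mean < s.v_max < 500.0

    def test_vmax_at_least_vmean(self, small_trial_set):
        for t in small_trial_set[:40]:
            s = fk.summarize_kinematics(t.profile)
            assert s.v_max >= s.v_mean

    def test_empty_subset_rejected_with_segment_name(self):
        n = 10
        p = fk.SpeedProfile("f", np.arange(n) * 0.01, np.ones(n), np.zeros(n), np.ones(n, bool))
        with pytest.raises(ValueError, match="control"):
            fk.summarize_kinematics(p, subset=np.zeros(n, bool), segment="control")
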