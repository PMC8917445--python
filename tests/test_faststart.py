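"""Response-window extraction, valley threshold and the 7-frame rule."""

import numpy as np
import pytest
from scipy.optimize import minimize_scalar
from scipy.stats import norm

import fastkin as fk
from fastkin.faststart import (
    CLASSIFY_WINDOW,
    DEFAULT_DT,
    FastStartTrial,
    classify_response,
    estimate_response_threshold,
    extract_response_window,
    mean_speed_curve,
    sensitivity_sweep,
    summarize_faststarts,
)
from fastkin.kinematics import SpeedProfile


def _profile(speed, dt=DEFAULT_DT, valid=None):
    speed = np.asarray(speed, float)
    n = len(speed)
    return SpeedProfile(
        "f", np.arange(n) * dt, speed, np.zeros(n), np.ones(n, bool) if valid is None else valid
    )


def _trial(speed, **kw):
    return FastStartTrial(fish_id="f", trial_index=1, profile=_profile(speed), **kw)


class TestResponseWindow:
    def test_default_dt_gives_56_frames(self):
        # independent count: number of grid points i*dt in [0, 0.157]
        expected = int(np.floor(0.157 / DEFAULT_DT)) + 1
        assert expected == 56
        w = extract_response_window(_trial(np.zeros(89)))
        assert w.n_frames == 56

    def test_profile_shorter_than_window_rejected(self):
        with pytest.raises(ValueError, match="0.157"):
            extract_response_window(_trial(np.zeros(30)))

    def test_degenerate_window_single_frame(self):
        w = extract_response_window(_trial(np.zeros(89)), window=(0.0, 0.0))
        assert w.n_frames == 1


class TestMeanSpeedCurve:
    def test_identical_profiles_mean_is_either(self):
        sp = np.linspace(0, 50, 89)
        mean, _ = mean_speed_curve([_trial(sp), _trial(sp)])
        np.testing.assert_allclose(mean, sp[:56])

    def test_flat_profiles_tie_break_to_first_frame(self):
        mean, peak = mean_speed_curve([_trial(np.full(89, 5.0))] * 3)
        assert peak == 0

    def test_peak_near_true_mean_pulse_peak(self, small_trial_set):
        responders = [t for t in small_trial_set if t.truth]
        _, peak = mean_speed_curve(responders)
        # true pulses peak at latency (~0.085 s) + rise (0.020 s)
        true_peak_frame = round(0.105 / DEFAULT_DT)
        assert abs(peak - true_peak_frame) <= 2

    def test_needs_two_trials(self):
        with pytest.raises(ValueError):
            mean_speed_curve([_trial(np.zeros(89))])


class TestValleyThreshold:
    def test_disjoint_blocks_threshold_in_gap(self):
        rng = np.random.default_rng(1)
        speeds = np.concatenate(
            [rng.uniform(0, 40, 4000), rng.uniform(120, 200, 2000)]
        )
        thr = estimate_response_threshold(speeds)
        assert not thr.fallback
        assert 40.0 < thr.threshold < 120.0

    def test_unimodal_input_falls_back_to_default(self):
        rng = np.random.default_rng(2)
        thr = estimate_response_threshold(rng.normal(50, 5, 5000))
        assert thr.fallback
        assert thr.threshold == 60.0

    def test_valley_strictly_between_peaks(self):
        rng = np.random.default_rng(3)
        speeds = np.abs(
            np.concatenate([rng.normal(20, 8, 10000), rng.normal(150, 35, 5000)])
        )
        thr = estimate_response_threshold(speeds)
        p1, p2 = thr.peak_indices
        assert p1 < thr.valley_index < p2
        centre = 0.5 * (thr.bin_edges[thr.valley_index] + thr.bin_edges[thr.valley_index + 1])
        assert thr.threshold == centre

    def test_recovery_on_well_separated_mixture(self):
        """Valley localization on a mixture with a count-rich valley
        (valley density ~24% of the smaller peak)."""
        w1, m1, s1 = 2 / 3, 20.0, 8.0
        w2, m2, s2 = 1 / 3, 90.0, 25.0
        pdf = lambda x: w1 * norm.pdf(x, m1, s1) + w2 * norm.pdf(x, m2, s2)
        grid = np.linspace(m1, m2, 20001)
        x0 = grid[np.argmin(pdf(grid))]
        valley = minimize_scalar(pdf, bounds=(x0 - 2, x0 + 2), method="bounded").x
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            comp = rng.random(15120) < w1
            x = np.abs(
                np.where(comp, rng.normal(m1, s1, 15120), rng.normal(m2, s2, 15120))
            )
            thr = estimate_response_threshold(x)
            hits += (not thr.fallback) and abs(thr.threshold - valley) <= 2 * thr.bin_width
        assert hits >= 95

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            estimate_response_threshold(np.array([]))


class TestClassification:
    def test_boundary_is_strict(self):
        t59 = _trial(np.full(89, 59.0))
        t61 = _trial(np.full(89, 61.0))
        for rule in ("mean", "any", "all"):
            assert classify_response(t59, 60.0, peak_frame=28, rule=rule) is False
            assert classify_response(t61, 60.0, peak_frame=28, rule=rule) is True

    def test_window_clipped_at_interval_edge_sets_flag(self):
        t = _trial(np.full(89, 100.0))
        classify_response(t, 60.0, peak_frame=1)
        assert t.edge_clipped

    def test_no_valid_frames_unclassifiable(self):
        valid = np.ones(89, bool)
        valid[20:40] = False
        t = FastStartTrial(fish_id="f", trial_index=1, profile=_profile(np.full(89, 100.0), valid=valid))
        assert classify_response(t, 60.0, peak_frame=30, win=7) is None
        assert t.meta["unclassifiable"]

    def test_disjoint_mixture_classified_without_error(self, disjoint_trial_set):
        trials, thr, _ = fk.classify_trials(disjoint_trial_set, threshold=60.0)
        assert all(t.response == t.truth for t in trials)

    def test_rule_ordering_nested(self, small_trial_set):
        _, peak = mean_speed_curve(small_trial_set)
        sets = {}
        for rule in ("all", "mean", "any"):
            for t in small_trial_set:
                classify_response(t, 60.0, peak, rule=rule)
            sets[rule] = {id(t) for t in small_trial_set if t.response}
        assert sets["all"] <= sets["mean"] <= sets["any"]

    def test_response_count_monotone_in_threshold(self, small_trial_set):
        _, peak = mean_speed_curve(small_trial_set)
        for rule in ("all", "mean", "any"):
            counts = []
            for thr in (0.0, 20.0, 40.0, 60.0, 80.0, 120.0, np.inf):
                for t in small_trial_set:
                    classify_response(t, thr, peak, rule=rule)
                counts.append(sum(bool(t.response) for t in small_trial_set))
            assert all(a >= b for a, b in zip(counts, counts[1:]))
            assert counts[0] == len(small_trial_set)  # threshold 0: any motion
            assert counts[-1] == 0  # infinite threshold


class TestSummaries:
    def test_summary_counts_conserved(self, small_trial_set):
        trials, _, _ = fk.classify_trials(small_trial_set)
        summaries, rates = summarize_faststarts(trials)
        n_resp = sum(bool(t.response) for t in trials)
        assert len(summaries) == n_resp
        assert rates["n_trials"].sum() == len(trials)
        assert rates["n_responses"].sum() == n_resp

    def test_responder_fraction_close_to_one_third(self, small_trial_set):
        trials, _, _ = fk.classify_trials(small_trial_set)
        frac = np.mean([bool(t.response) for t in trials])
        n = len(trials)
        tol = 3 * np.sqrt((1 / 3) * (2 / 3) / n)
        assert abs(frac - 1 / 3) < tol

    def test_all_responders_means_all_summarized(self, disjoint_trial_set):
        trials, _, _ = fk.classify_trials(disjoint_trial_set, threshold=60.0)
        responders = [t for t in trials if t.response]
        summaries, _ = summarize_faststarts(responders)
        assert len(summaries) == len(responders)


class TestSensitivitySweep:
    def test_disjoint_mixture_robust_across_thresholds(self, disjoint_trial_set):
        # the generated gap spans ~30-120 mm/s, so 40/60/80 all agree
        table = sensitivity_sweep(disjoint_trial_set, [40.0, 60.0, 80.0], rules=("mean",))
        assert table["n_responses"].nunique() == 1

    def test_counts_monotone_within_each_rule(self, small_trial_set):
        table = sensitivity_sweep(small_trial_set, [0.0, 30.0, 60.0, 90.0, np.inf])
        for _, g in table.groupby("rule"):
            counts = g.sort_values("threshold")["n_responses"].to_numpy()
            assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_requires_a_threshold(self, small_trial_set):
        with pytest.raises(ValueError):
            sensitivity_sweep(small_trial_set, [])
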