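"""Segmentation, dish-array tracking and calibration."""

import numpy as np
import pytest

import fastkin as fk
from fastkin.tracking import (
    Dish,
    DishLayout,
    SegmentationParams,
    calibrate_scale,
    estimate_background,
    segment_silhouette,
    track_frames,
)


def _roi(shape, centre, radius):
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (rr - centre[0]) ** 2 + (cc - centre[1]) ** 2 <= radius**2


class TestBackground:
    def test_identical_frames_return_that_frame(self):
        frame = np.full((20, 20), 123.0)
        bg = estimate_background(np.stack([frame] * 12))
        np.testing.assert_array_equal(bg, frame)

    def test_median_ignores_transient_fish(self):
        frames = np.full((15, 30, 30), 200.0)
        for i in range(15):  # dark square occupying each spot in 1/15 frames
            frames[i, 5 + i : 9 + i, 10:14] = 60.0
        bg = estimate_background(frames)
        np.testing.assert_array_equal(bg, np.full((30, 30), 200.0))

    def test_noise_sd2_background_error_within_2_grey_levels(self):
        rng = np.random.default_rng(0)
        clean = np.full((40, 40), 180.0)
        frames = clean + rng.normal(0, 2.0, (60, 40, 40))
        for i in range(60):  # moving dark block
            frames[i, (i % 30) : (i % 30) + 6, 8:14] = 60.0
        bg = estimate_background(frames)
        err = np.abs(bg - clean)
        assert np.quantile(err, 0.99) <= 2.0

    def test_too_few_frames_rejected_naming_minimum(self):
        with pytest.raises(ValueError, match="11"):
            estimate_background(np.zeros((5, 10, 10)))


class TestSegmentation:
    def test_frame_equal_to_background_gives_no_detection(self):
        bg = np.full((40, 40), 150.0)
        params = SegmentationParams(threshold_mode="otsu")
        mask, cen = segment_silhouette(bg.copy(), bg, params=params)
        assert mask is None and cen is None

    def test_blank_backlit_frame_gives_no_detection(self):
        frame = np.full((40, 40), 230.0)
        mask, cen = segment_silhouette(frame)
        assert mask is None and cen is None

    def test_speck_below_min_area_excluded(self):
        # two components: a 9x11 fish block and a 2x2 food speck;
        # oracle centroids are the blocks' analytic centres
        frame = np.full((60, 60), 220.0)
        frame[20:29, 30:41] = 70.0  # fish, area 99
        frame[45:47, 10:12] = 70.0  # speck, area 4
        params = SegmentationParams(min_area_px=10)
        mask, cen = segment_silhouette(frame, params=params)
        assert mask.sum() == 99
        assert cen == pytest.approx((24.0, 35.0))

    def test_background_subtraction_mode_matches_backlit(self):
        frame = np.full((60, 60), 220.0)
        frame[20:29, 30:41] = 70.0
        bg = np.full((60, 60), 220.0)
        _, cen = segment_silhouette(
            frame, bg, params=SegmentationParams(threshold_mode="otsu")
        )
        assert cen == pytest.approx((24.0, 35.0))

    def test_rendered_ellipse_subpixel_centroid(self):
        lay = fk.make_layout("1x1", px_per_mm=4.0)
        n = 12
        tr = fk.Track(
            "s", "d", np.arange(n), np.arange(n) / 353.0,
            np.full(n, 3.3), np.full(n, -2.7), np.ones(n, bool),
        )
        frames, truth = fk.render_frames(tr, fk.RenderParams(layout=lay, noise_sd=0.0))
        dish = lay.dishes[0]
        roi = _roi(frames[0].shape, dish.centre_px, dish.radius_px)
        _, cen = segment_silhouette(frames[0], roi=roi)
        t = truth.iloc[0]
        assert np.hypot(cen[0] - t.row_px, cen[1] - t.col_px) < 0.5


class TestTrackFrames:
    def test_roundtrip_noise_free_subpixel(self):
        sim = fk.simulate_fast_start_trials(
            fk.FastStartSimParams(n_fish=5, trials_per_fish=1, seed=1)
        )
        tracks = [t.track for t in sim]
        lay = fk.make_layout("1x5", px_per_mm=4.0)
        frames, _ = fk.render_frames(tracks, fk.RenderParams(layout=lay, noise_sd=0.0))
        rec = track_frames(frames, lay, frame_rate=1 / tracks[0].dt)
        err = np.concatenate(
            [
                (np.hypot(r.x_mm - t.x_mm, r.y_mm - t.y_mm) * lay.px_per_mm)[r.valid]
                for t, r in zip(tracks, rec)
            ]
        )
        assert np.sqrt((err**2).mean()) < 0.5

    def test_roundtrip_with_noise(self):
        for seed in (2, 3):
            sim = fk.simulate_fast_start_trials(
                fk.FastStartSimParams(n_fish=9, trials_per_fish=1, seed=seed)
            )
            tracks = [t.track for t in sim]
            lay = fk.make_layout("3x3", px_per_mm=4.0)
            frames, _ = fk.render_frames(
                tracks, fk.RenderParams(layout=lay, noise_sd=8.0, seed=seed)
            )
            rec = track_frames(frames, lay, frame_rate=1 / tracks[0].dt)
            err = np.concatenate(
                [
                    (np.hypot(r.x_mm - t.x_mm, r.y_mm - t.y_mm) * 4.0)[r.valid]
                    for t, r in zip(tracks, rec)
                ]
            )
            assert np.sqrt((err**2).mean()) < 1.5

    def test_nine_dish_composite_assignment(self, layout_3x3):
        sim = fk.simulate_fast_start_trials(
            fk.FastStartSimParams(n_fish=9, trials_per_fish=1, seed=4)
        )
        tracks = [t.track for t in sim]
        frames, _ = fk.render_frames(tracks, fk.RenderParams(layout=layout_3x3))
        rec = track_frames(frames, layout_3x3, frame_rate=1 / tracks[0].dt)
        assert [r.dish_id for r in rec] == [d.dish_id for d in layout_3x3.dishes]
        # each dish recovers its own fish, not a neighbour's
        for t, r in zip(tracks, rec):
            e = np.hypot(r.x_mm - t.x_mm, r.y_mm - t.y_mm) * 4.0
            assert e[r.valid].max() < 2.0

    def test_short_gap_interpolated_and_flagged(self):
        sim = fk.simulate_fast_start_trials(
            fk.FastStartSimParams(n_fish=1, trials_per_fish=1, responder_fraction=1.0, seed=6)
        )
        tr = sim[0].track
        lay = fk.make_layout("1x1", px_per_mm=4.0)
        frames, _ = fk.render_frames(tr, fk.RenderParams(layout=lay))
        blank = np.full_like(frames[0], 230)
        frames[40] = blank
        frames[41] = blank
        rec = track_frames(frames, lay, max_gap=3, frame_rate=1 / tr.dt)[0]
        assert rec.valid[40] and rec.valid[41]
        assert rec.gap_filled[40] and rec.gap_filled[41]
        assert not rec.gap_filled[39]
        # interpolation stays close to the true positions
        assert np.hypot(rec.x_mm[40] - tr.x_mm[40], rec.y_mm[40] - tr.y_mm[40]) < 1.0

    def test_long_gap_left_invalid(self):
        sim = fk.simulate_fast_start_trials(
            fk.FastStartSimParams(n_fish=1, trials_per_fish=1, seed=6)
        )
        tr = sim[0].track
        lay = fk.make_layout("1x1", px_per_mm=4.0)
        frames, _ = fk.render_frames(tr, fk.RenderParams(layout=lay))
        blank = np.full_like(frames[0], 230)
        for i in range(30, 36):
            frames[i] = blank
        rec = track_frames(frames, lay, max_gap=3, frame_rate=1 / tr.dt)[0]
        assert not rec.valid[30:36].any()

    def test_monotone_time_and_containment(self, layout_3x3):
        sim = fk.simulate_fast_start_trials(
            fk.FastStartSimParams(n_fish=9, trials_per_fish=1, seed=8)
        )
        frames, _ = fk.render_frames([t.track for t in sim], fk.RenderParams(layout=layout_3x3))
        for r in track_frames(frames, layout_3x3):
            assert (np.diff(r.time_s) > 0).all()
            rad = np.hypot(r.x_mm[r.valid], r.y_mm[r.valid])
            assert (rad <= layout_3x3.diameter_mm / 2 + 0.5).all()


class TestLayoutAndCalibration:
    def test_px_per_mm_arithmetic(self):
        for radius, diam in ((175.0, 35.0), (275.0, 55.0)):
            lay = DishLayout(
                dishes=(Dish("d0", (200.0, 200.0), radius),),
                px_per_mm=10.0,
                diameter_mm=diam,
            )
            assert calibrate_scale(lay) == pytest.approx(10.0)

    def test_inconsistent_scales_listed(self):
        lay = DishLayout(
            dishes=(
                Dish("a", (100.0, 100.0), 72.8),
                Dish("b", (100.0, 260.0), 67.2),
            ),
            px_per_mm=4.0,
            diameter_mm=35.0,
        )
        with pytest.raises(ValueError, match="inconsistent"):
            calibrate_scale(lay, max_cv=0.03)

    def test_overlapping_dishes_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            DishLayout(
                dishes=(
                    Dish("a", (100.0, 100.0), 70.0),
                    Dish("b", (100.0, 150.0), 70.0),
                ),
                px_per_mm=4.0,
                diameter_mm=35.0,
            )

    def test_layout_patterns(self):
        assert len(fk.make_layout("3x3").dishes) == 9
        assert len(fk.make_layout("1x5").dishes) == 5
        with pytest.raises(ValueError, match="pattern"):
            fk.make_layout("lots")
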