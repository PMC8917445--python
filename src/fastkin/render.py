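"""Synthetic dorsal-view frame rendering.

Draws each fish as a filled ellipse (a newborn is ~7 mm long and a few
mm wide seen from above) centred on its true centroid and oriented
along its instantaneous heading, inside a uniform-background circular
dish, optionally with additive Gaussian pixel noise. The analytic
centroid of every fish in every frame is emitted as ground truth, which
is what makes the tracker testable end to end.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tracking import DishLayout, Track


@dataclass(frozen=True)
class RenderParams:
    """Appearance of the rendered frames.

    Grey levels are 8-bit; ``noise_sd`` is the standard deviation of
    additive Gaussian noise in grey levels, applied before clipping.
    """

    layout: DishLayout
    fish_length_mm: float = 7.0
    fish_aspect: float = 0.35
    background_grey: int = 230
    fish_grey: int = 70
    noise_sd: float = 0.0
    rim_grey: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        for g in (self.background_grey, self.fish_grey, self.rim_grey):
            if not 0 <= g <= 255:
                raise ValueError("grey levels must be within 0..255")
        if self.fish_length_mm >= self.layout.diameter_mm:
            raise ValueError("fish must fit inside the dish")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def _headings(track: Track) -> np.ndarray:
    """Per-frame heading from the displacement; holds the last heading
    through stationary stretches (0 for a fully stationary track)."""
    pos = track.positions()
    n = len(pos)
    theta = np.zeros(n)
    current = 0.0
    for i in range(n):
        j = min(i + 1, n - 1)
        k = max(i - 1, 0)
        d = pos[j] - pos[k]
        if np.hypot(*d) > 1e-9:
            current = float(np.arctan2(d[1], d[0]))
        theta[i] = current
    return theta


def _draw_ellipse(
    canvas: np.ndarray,
    centre_rc: tuple[float, float],
    theta: float,
    a_px: float,
    b_px: float,
    grey: int,
) -> None:
    r0 = int(np.floor(centre_rc[0] - a_px - 2))
    r1 = int(np.ceil(centre_rc[0] + a_px + 2))
    c0 = int(np.floor(centre_rc[1] - a_px - 2))
    c1 = int(np.ceil(centre_rc[1] + a_px + 2))
    r0, c0 = max(r0, 0), max(c0, 0)
    r1, c1 = min(r1, canvas.shape[0]), min(c1, canvas.shape[1])
    rr, cc = np.mgrid[r0:r1, c0:c1]
    dy = rr - centre_rc[0]
    dx = cc - centre_rc[1]
    # heading theta is measured in (x, y) = (col, row) coordinates
    u = dx * np.cos(theta) + dy * np.sin(theta)
    w = -dx * np.sin(theta) + dy * np.cos(theta)
    inside = (u / a_px) ** 2 + (w / b_px) ** 2 <= 1.0
    canvas[r0:r1, c0:c1][inside] = grey


def render_frames(
    tracks: Track | list[Track],
    params: RenderParams,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Render a frame sequence from one track per dish.

    Tracks are assigned to the layout's dishes in order (a single track
    renders into the first dish). All tracks must have the same frame
    count. A track point outside its dish is rejected with the frame
    index. Returns the uint8 stack (n, H, W) and a ground-truth table
    with the true centroid of every fish in pixel coordinates per frame.
    """
    if isinstance(tracks, Track):
        tracks = [tracks]
    layout = params.layout
    if len(tracks) > len(layout.dishes):
        raise ValueError(
            f"{len(tracks)} tracks but layout has only {len(layout.dishes)} dishes"
        )
    n_frames = tracks[0].n_frames
    for tr in tracks:
        if tr.n_frames != n_frames:
            raise ValueError("all tracks must have the same number of frames")
    radius_mm = layout.diameter_mm / 2.0
    for tr, dish in zip(tracks, layout.dishes):
        rad = np.hypot(tr.x_mm, tr.y_mm)
        bad = np.flatnonzero(rad > radius_mm)
        if bad.size:
            raise ValueError(
                f"track {tr.fish_id} leaves dish {dish.dish_id} at frame {bad[0]}"
            )
    H, W = layout.frame_shape
    rng = np.random.default_rng(params.seed)
    a_px = params.fish_length_mm * layout.px_per_mm / 2.0
    b_px = a_px * params.fish_aspect

    base = np.full((H, W), float(params.background_grey))
    rr, cc = np.mgrid[0:H, 0:W]
    for dish in layout.dishes:
        dist = np.hypot(rr - dish.centre_px[0], cc - dish.centre_px[1])
        rim = (dist >= dish.radius_px - 2) & (dist <= dish.radius_px)
        base[rim] = params.rim_grey

    headings = [_headings(tr) for tr in tracks]
    frames = np.empty((n_frames, H, W), dtype=np.uint8)
    truth_rows = []
    for i in range(n_frames):
        canvas = base.copy()
        for tr, dish, theta in zip(tracks, layout.dishes, headings):
            row = dish.centre_px[0] + tr.y_mm[i] * layout.px_per_mm
            col = dish.centre_px[1] + tr.x_mm[i] * layout.px_per_mm
            _draw_ellipse(canvas, (row, col), theta[i], a_px, b_px, params.fish_grey)
            truth_rows.append(
                {
                    "frame": i,
                    "fish_id": tr.fish_id,
                    "dish_id": dish.dish_id,
                    "row_px": row,
                    "col_px": col,
                    "heading_rad": theta[i],
                }
            )
        if params.noise_sd > 0:
            canvas = canvas + rng.normal(0.0, params.noise_sd, size=canvas.shape)
        frames[i] = np.clip(np.round(canvas), 0, 255).astype(np.uint8)
    return frames, pd.DataFrame(truth_rows)
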