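"""Centroid tracking of single fish in Petri-dish arrays.

Each frame holds one or more circular dishes (35 mm for startle trials,
55 mm for feeding trials), each containing a single newborn fish filmed
from above. Tracking is classical and deterministic: the recordings are
LED-backlit, so by default the fish is segmented as a dark silhouette
below an automatic within-ROI intensity threshold, keeping the largest
connected component within an area gate; temporal-background
subtraction (median or high quantile) is available for scenes without a
clean bright field. The component's unweighted pixel centroid is the
fish's centre of mass.

Conventions
-----------
Image coordinates are 0-based (row, col). Physical coordinates are mm
with the origin at the dish centre, x increasing with column (rightwards)
and y increasing with row (downwards in the image).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

logger = logging.getLogger(__name__)

#: smallest dish diameter (mm) used in the startle set-up
FASTSTART_DISH_MM = 35.0
#: dish diameter (mm) used for housing and feeding trials
FEEDING_DISH_MM = 55.0


@dataclass(frozen=True)
class Dish:
    dish_id: str
    centre_px: tuple[float, float]  # (row, col)
    radius_px: float
    grid_label: str = ""


@dataclass(frozen=True)
class DishLayout:
    """Geometry of a multi-dish recording arena.

    Parameters
    ----------
    dishes
        Dish positions in pixel coordinates.
    px_per_mm
        Spatial calibration shared by all dishes.
    diameter_mm
        Nominal dish diameter; ``radius_px`` of every dish must agree
        with it through ``px_per_mm`` to within 5 %.
    """

    dishes: tuple[Dish, ...]
    px_per_mm: float
    diameter_mm: float

    def __post_init__(self) -> None:
        if self.px_per_mm <= 0:
            raise ValueError("px_per_mm must be positive")
        for d in self.dishes:
            expected = self.diameter_mm * self.px_per_mm / 2.0
            if not math.isclose(d.radius_px, expected, rel_tol=0.05):
                raise ValueError(
                    f"dish {d.dish_id}: radius {d.radius_px} px inconsistent with "
                    f"diameter {self.diameter_mm} mm at {self.px_per_mm} px/mm"
                )
        for i, a in enumerate(self.dishes):
            for b in self.dishes[i + 1 :]:
                dist = math.hypot(
                    a.centre_px[0] - b.centre_px[0], a.centre_px[1] - b.centre_px[1]
                )
                if dist < a.radius_px + b.radius_px:
                    raise ValueError(f"dishes {a.dish_id} and {b.dish_id} overlap")

    @property
    def frame_shape(self) -> tuple[int, int]:
        rows = max(d.centre_px[0] + d.radius_px for d in self.dishes)
        cols = max(d.centre_px[1] + d.radius_px for d in self.dishes)
        margin = 0.15 * self.dishes[0].radius_px
        return int(math.ceil(rows + margin)), int(math.ceil(cols + margin))


def make_layout(
    pattern: str,
    px_per_mm: float = 4.0,
    diameter_mm: float = FASTSTART_DISH_MM,
    spacing_factor: float = 1.15,
) -> DishLayout:
    """Build a regular ``"3x3"`` or ``"1x5"`` dish layout.

    The 3x3 arrangement mirrors the feeding set-up (nine dishes on a
    plate); 1x5 mirrors the startle set-up (five dishes in a row).
    Any ``"<rows>x<cols>"`` string is accepted.
    """
    try:
        n_rows, n_cols = (int(s) for s in pattern.lower().split("x"))
    except ValueError as exc:
        raise ValueError(f"pattern must look like '3x3', got {pattern!r}") from exc
    radius = diameter_mm * px_per_mm / 2.0
    pitch = 2.0 * radius * spacing_factor
    dishes = []
    for r in range(n_rows):
        for c in range(n_cols):
            centre = (radius * 1.1 + r * pitch, radius * 1.1 + c * pitch)
            dishes.append(
                Dish(
                    dish_id=f"d{r}{c}",
                    centre_px=centre,
                    radius_px=radius,
                    grid_label=f"r{r}c{c}",
                )
            )
    return DishLayout(dishes=tuple(dishes), px_per_mm=px_per_mm, diameter_mm=diameter_mm)


@dataclass
class Track:
    """Time-stamped centroid trajectory of one fish in one dish (mm).

    ``valid`` marks frames with a usable position; ``gap_filled`` marks
    interior frames whose position was linearly interpolated across a
    short detection gap (never longer than the tracker's ``max_gap``).
    """

    fish_id: str
    dish_id: str
    frames: np.ndarray
    time_s: np.ndarray
    x_mm: np.ndarray
    y_mm: np.ndarray
    valid: np.ndarray
    gap_filled: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.x_mm = np.asarray(self.x_mm, dtype=float)
        self.y_mm = np.asarray(self.y_mm, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.gap_filled is None:
            self.gap_filled = np.zeros(len(self.time_s), dtype=bool)
        self.gap_filled = np.asarray(self.gap_filled, dtype=bool)
        n = len(self.time_s)
        if not all(len(a) == n for a in (self.frames, self.x_mm, self.y_mm, self.valid, self.gap_filled)):
            raise ValueError("all Track arrays must have equal length")
        if n > 1:
            dts = np.diff(self.time_s)
            if np.any(dts <= 0):
                raise ValueError("time_s must be strictly increasing")
            if not np.allclose(dts, dts[0], rtol=1e-6, atol=1e-12):
                raise ValueError("time_s must advance with a constant frame interval")

    @property
    def n_frames(self) -> int:
        return len(self.time_s)

    @property
    def dt(self) -> float:
        if self.n_frames < 2:
            raise ValueError("dt undefined for a track with fewer than 2 frames")
        return float(self.time_s[1] - self.time_s[0])

    def positions(self) -> np.ndarray:
        """(n, 2) array of (x, y) in mm."""
        return np.column_stack([self.x_mm, self.y_mm])


@dataclass(frozen=True)
class SegmentationParams:
    """Knobs of the silhouette segmenter.

    ``threshold_mode``:

    * ``"backlit"`` (default) — the recordings are LED-backlit, so the
      fish is a dark silhouette on a bright field; pixels below an
      automatic (Otsu) within-ROI intensity threshold are foreground.
      Needs no background model and works for a stationary fish.
    * ``"otsu"`` — threshold ``|frame - background|`` with an automatic
      within-ROI threshold (floored at ``min_contrast`` so sensor noise
      alone never yields a detection).
    * ``"fixed"`` — threshold ``|frame - background|`` at
      ``fixed_threshold`` grey levels.

    The area gate rejects both specks (dropped food, debris) and
    implausibly large components (e.g. a noise split of an empty dish).
    """

    min_area_px: int = 20
    max_area_px: int = 5_000
    threshold_mode: str = "backlit"  # "backlit" | "otsu" | "fixed"
    fixed_threshold: float = 20.0
    min_contrast: float = 10.0
    weighted_centroid: bool = False


def estimate_background(
    frames: np.ndarray,
    roi: np.ndarray | None = None,
    method: str = "median",
    quantile: float = 0.9,
) -> np.ndarray:
    """Per-pixel temporal background of a frame stack.

    ``method="median"`` is robust as long as the fish occupies each
    pixel in fewer than half the frames. In short clips a fish that
    dwells in one spot (e.g. before a startle stimulus) can exceed
    that, eroding its own silhouette; ``method="quantile"`` takes a
    high temporal quantile instead, which a *dark* fish on a light
    background cannot contaminate unless it occupies a pixel in more
    than ``1 - quantile`` of the frames.

    Parameters
    ----------
    frames
        (n, H, W) stack.
    roi
        Optional boolean (H, W) mask; pixels outside are returned as 0.
    """
    frames = np.asarray(frames)
    if frames.ndim != 3:
        raise ValueError("frames must be a (n, H, W) stack")
    if frames.shape[0] < 11:
        raise ValueError(
            f"background estimation needs at least 11 frames, got {frames.shape[0]}"
        )
    if method == "median":
        bg = np.median(frames.astype(np.float64), axis=0)
    elif method == "quantile":
        bg = np.quantile(frames.astype(np.float64), quantile, axis=0)
    else:
        raise ValueError(f"unknown background method {method!r}")
    if roi is not None:
        bg = np.where(roi, bg, 0.0)
    return bg


def segment_silhouette(
    frame: np.ndarray,
    background: np.ndarray | None = None,
    roi: np.ndarray | None = None,
    params: SegmentationParams = SegmentationParams(),
) -> tuple[np.ndarray | None, tuple[float, float] | None]:
    """Segment the fish silhouette in one frame.

    Builds a foreground map according to ``params.threshold_mode``
    (dark-silhouette intensity threshold by default, or background
    subtraction), keeps the largest connected component whose area lies
    within the gate, and returns its binary mask and centroid
    ``(row, col)``. Returns ``(None, None)`` when nothing qualifies —
    absence of a detection is a flag, not an error.
    """
    img = frame.astype(np.float64)
    if params.threshold_mode == "backlit":
        vals = img[roi] if roi is not None else img.ravel()
        if vals.size == 0 or np.ptp(vals) < params.min_contrast:
            return None, None
        thr = float(threshold_otsu(vals))
        # darkness below the bright field is the foreground "contrast"
        diff = np.clip(float(vals.max()) - img, 0.0, None)
        mask = img < thr
        if roi is not None:
            mask &= roi
    else:
        if background is None:
            raise ValueError("background is required unless threshold_mode='backlit'")
        diff = np.abs(img - background.astype(np.float64))
        if roi is not None:
            diff = np.where(roi, diff, 0.0)
        if params.threshold_mode == "fixed":
            thr = params.fixed_threshold
        elif params.threshold_mode == "otsu":
            vals = diff[roi] if roi is not None else diff.ravel()
            if vals.size == 0 or np.ptp(vals) == 0:
                return None, None
            thr = max(float(threshold_otsu(vals)), params.min_contrast)
        else:
            raise ValueError(f"unknown threshold_mode {params.threshold_mode!r}")
        mask = diff > thr
    if not mask.any():
        return None, None
    labels = label(mask, connectivity=2)
    best = None
    for region in regionprops(labels, intensity_image=diff):
        if params.min_area_px <= region.area <= params.max_area_px:
            if best is None or region.area > best.area:
                best = region
    if best is None:
        return None, None
    centroid = best.centroid_weighted if params.weighted_centroid else best.centroid
    return labels == best.label, (float(centroid[0]), float(centroid[1]))


def _fill_gaps(values: np.ndarray, valid: np.ndarray, max_gap: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Linearly interpolate interior invalid runs of length <= max_gap."""
    values = values.copy()
    valid_out = valid.copy()
    filled = np.zeros(len(values), dtype=bool)
    idx = np.flatnonzero(valid)
    if idx.size < 2:
        return values, valid_out, filled
    i = 0
    n = len(values)
    while i < n:
        if valid[i]:
            i += 1
            continue
        j = i
        while j < n and not valid[j]:
            j += 1
        # run [i, j) invalid; interior iff bounded by valid frames on both sides
        if i > 0 and j < n and (j - i) <= max_gap:
            left, right = i - 1, j
            for k in range(i, j):
                w = (k - left) / (right - left)
                values[k] = (1 - w) * values[left] + w * values[right]
            valid_out[i:j] = True
            filled[i:j] = True
        i = j
    return values, valid_out, filled


def track_frames(
    frames: np.ndarray,
    layout: DishLayout,
    max_gap: int = 3,
    seg_params: SegmentationParams = SegmentationParams(),
    frame_rate: float = 353.0,
    fish_ids: dict[str, str] | None = None,
    bg_method: str = "quantile",
    bg_quantile: float = 0.9,
) -> list[Track]:
    """Track every dish of a layout through a frame stack.

    Returns one :class:`Track` per dish, in layout order, with positions
    in mm relative to the dish centre. Detection gaps up to ``max_gap``
    frames are linearly interpolated and flagged ``gap_filled``; longer
    gaps stay invalid. A dish with zero detections yields an all-invalid
    track and a warning.

    The default background is a high temporal quantile rather than the
    median: the clips here are short and a fish dwelling in one spot
    for half the clip would erode its own silhouette from a median
    background (this assumes the fish is darker than the background, as
    in dorsal LED-backlit recordings; pass ``bg_method="median"``
    otherwise).
    """
    frames = np.asarray(frames)
    n_frames, H, W = frames.shape
    for d in layout.dishes:
        r, c = d.centre_px
        if r + d.radius_px > H + 1 or c + d.radius_px > W + 1:
            raise ValueError(f"dish {d.dish_id} does not fit in {H}x{W} frames")
    dt = 1.0 / frame_rate
    tracks: list[Track] = []
    for dish in layout.dishes:
        r0 = max(int(dish.centre_px[0] - dish.radius_px) - 2, 0)
        r1 = min(int(math.ceil(dish.centre_px[0] + dish.radius_px)) + 2, H)
        c0 = max(int(dish.centre_px[1] - dish.radius_px) - 2, 0)
        c1 = min(int(math.ceil(dish.centre_px[1] + dish.radius_px)) + 2, W)
        crop = frames[:, r0:r1, c0:c1]
        rr, cc = np.mgrid[r0:r1, c0:c1]
        roi = (rr - dish.centre_px[0]) ** 2 + (cc - dish.centre_px[1]) ** 2 <= dish.radius_px**2
        if seg_params.threshold_mode == "backlit":
            bg = None
        else:
            bg = estimate_background(crop, roi, method=bg_method, quantile=bg_quantile)
        xs = np.full(n_frames, np.nan)
        ys = np.full(n_frames, np.nan)
        valid = np.zeros(n_frames, dtype=bool)
        for i in range(n_frames):
            _, cen = segment_silhouette(crop[i], bg, roi, seg_params)
            if cen is not None:
                row_px, col_px = cen[0] + r0, cen[1] + c0
                xs[i] = (col_px - dish.centre_px[1]) / layout.px_per_mm
                ys[i] = (row_px - dish.centre_px[0]) / layout.px_per_mm
                valid[i] = True
        if not valid.any():
            logger.warning("dish %s: no detections in %d frames", dish.dish_id, n_frames)
        xs, vx, fx = _fill_gaps(xs, valid, max_gap)
        ys, _, _ = _fill_gaps(ys, valid, max_gap)
        fid = (fish_ids or {}).get(dish.dish_id, f"fish_{dish.dish_id}")
        xs = np.where(vx, xs, 0.0)
        ys = np.where(vx, ys, 0.0)
        tracks.append(
            Track(
                fish_id=fid,
                dish_id=dish.dish_id,
                frames=np.arange(n_frames),
                time_s=np.arange(n_frames) * dt,
                x_mm=xs,
                y_mm=ys,
                valid=vx,
                gap_filled=fx,
            )
        )
    return tracks


def calibrate_scale(layout: DishLayout, max_cv: float = 0.05) -> float:
    """Pixel-per-mm scale from dish geometry.

    Each dish implies ``px_per_mm = 2 * radius_px / diameter_mm``; the
    estimates must agree across dishes (coefficient of variation below
    ``max_cv``), otherwise the offending dishes are listed.
    """
    scales = np.array([2.0 * d.radius_px / layout.diameter_mm for d in layout.dishes])
    mean = float(scales.mean())
    if len(scales) > 1 and scales.std() / mean >= max_cv:
        offenders = [
            d.dish_id
            for d, s in zip(layout.dishes, scales)
            if abs(s - mean) / mean >= max_cv
        ]
        raise ValueError(f"inconsistent dish scales (CV >= {max_cv:.0%}): {offenders}")
    return mean
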