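"""Plain-text I/O: trajectory tables, layouts, events, frame sequences.

Trajectory CSVs use one schema regardless of origin (tracker output or
synthetic generator), so downstream stages are source-agnostic:
``fish_id, trial_id, frame, time_s, x_mm, y_mm, valid, gap_filled``.
Coordinates are mm with the origin at the dish centre, x rightwards and
y downwards in the image. Layouts are JSON; frames are individual PNGs.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .tracking import Dish, DishLayout, Track

TRACK_COLUMNS = ["fish_id", "trial_id", "frame", "time_s", "x_mm", "y_mm", "valid", "gap_filled"]


def write_tracks_csv(tracks: list[Track], path: str | Path, trial_ids=None) -> Path:
    """Write tracks to one long-format CSV (units documented in io module)."""
    rows = []
    for k, tr in enumerate(tracks):
        tid = trial_ids[k] if trial_ids is not None else 1
        rows.append(
            pd.DataFrame(
                {
                    "fish_id": tr.fish_id,
                    "trial_id": tid,
                    "frame": tr.frames,
                    "time_s": tr.time_s,
                    "x_mm": tr.x_mm,
                    "y_mm": tr.y_mm,
                    "valid": tr.valid.astype(int),
                    "gap_filled": tr.gap_filled.astype(int),
                }
            )
        )
    path = Path(path)
    pd.concat(rows, ignore_index=True)[TRACK_COLUMNS].to_csv(path, index=False)
    return path


def read_tracks_csv(path: str | Path) -> list[Track]:
    df = pd.read_csv(path)
    tracks = []
    for (fid, _tid), g in df.groupby(["fish_id", "trial_id"], sort=False):
        g = g.sort_values("frame")
        tracks.append(
            Track(
                fish_id=str(fid),
                dish_id="",
                frames=g["frame"].to_numpy(),
                time_s=g["time_s"].to_numpy(),
                x_mm=g["x_mm"].to_numpy(),
                y_mm=g["y_mm"].to_numpy(),
                valid=g["valid"].to_numpy().astype(bool),
                gap_filled=g["gap_filled"].to_numpy().astype(bool),
            )
        )
    return tracks


def write_layout(layout: DishLayout, path: str | Path) -> Path:
    path = Path(path)
    payload = {
        "px_per_mm": layout.px_per_mm,
        "diameter_mm": layout.diameter_mm,
        "dishes": [
            {
                "dish_id": d.dish_id,
                "centre_px": list(d.centre_px),
                "radius_px": d.radius_px,
                "grid_label": d.grid_label,
            }
            for d in layout.dishes
        ],
    }
    path.write_text(json.dumps(payload, indent=2), encoding="utf-8")
    return path


def read_layout(path: str | Path) -> DishLayout:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    dishes = tuple(
        Dish(
            dish_id=d["dish_id"],
            centre_px=tuple(d["centre_px"]),
            radius_px=d["radius_px"],
            grid_label=d.get("grid_label", ""),
        )
        for d in payload["dishes"]
    )
    return DishLayout(
        dishes=dishes,
        px_per_mm=payload["px_per_mm"],
        diameter_mm=payload["diameter_mm"],
    )


def write_frames(frames: np.ndarray, directory: str | Path, prefix: str = "frame") -> list[Path]:
    """Write a (n, H, W) uint8 stack as numbered PNGs."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, frame in enumerate(frames):
        p = directory / f"{prefix}_{i:05d}.png"
        iio.imwrite(p, frame)
        paths.append(p)
    return paths


def read_frames(directory: str | Path, pattern: str = "*.png") -> np.ndarray:
    paths = sorted(Path(directory).glob(pattern))
    if not paths:
        raise FileNotFoundError(f"no frames matching {pattern} in {directory}")
    return np.stack([iio.imread(p) for p in paths])


def write_events_csv(events: dict[str, tuple[float, float]], fish_id: str, path: str | Path) -> Path:
    rows = [
        {"fish_id": fish_id, "event": name, "t_start_s": s, "t_end_s": e}
        for name, (s, e) in events.items()
    ]
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def read_events_csv(path: str | Path) -> dict[str, dict[str, tuple[float, float]]]:
    """Events per fish: {fish_id: {event: (start_s, end_s)}}."""
    df = pd.read_csv(path)
    out: dict[str, dict[str, tuple[float, float]]] = {}
    for _, row in df.iterrows():
        out.setdefault(str(row["fish_id"]), {})[row["event"]] = (
            float(row["t_start_s"]),
            float(row["t_end_s"]),
        )
    return out
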