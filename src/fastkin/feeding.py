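"""Feeding-trial segmentation and per-period kinematics.

Each feeding recording has three consecutive phases: a 5-min control
period with no food, a short supply interval during which the
experimenter pipettes ~30 Artemia nauplii into the dish, and a 5-min
feeding period. The supply interval contains experimenter-induced
motion and is excised before any summary; control and feeding periods
are summarized separately so the effect of food availability can be
isolated.

Frames are assigned to periods by half-open intervals [start, end) on
the frame timestamp, so no frame is ever double-counted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kinematics import KinematicsSummary, SpeedProfile, summarize_kinematics

logger = logging.getLogger(__name__)

PERIODS = ("control", "supply", "feeding")
AGES = (0, 2, 7)
TREATMENTS = ("LF", "HF")


@dataclass
class FeedingSession:
    """One age-specific feeding recording of one fish.

    ``events`` maps each period name to its (start_s, end_s) interval;
    control precedes supply precedes feeding, pairwise disjoint.
    ``truth`` carries generator ground truth for synthetic sessions.
    """

    fish_id: str
    age_days: int
    treatment: str
    day: int
    profile: SpeedProfile
    events: dict
    dish_position: str = ""
    truth: dict | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.age_days not in AGES:
            raise ValueError(f"age_days must be one of {AGES}, got {self.age_days}")
        if self.treatment not in TREATMENTS:
            raise ValueError(f"treatment must be LF or HF, got {self.treatment!r}")
        missing = [p for p in PERIODS if p not in self.events]
        if missing:
            raise ValueError(f"events missing periods: {missing}")
        _check_events(self.events)


def _check_events(events: dict) -> None:
    intervals = [(p, *events[p]) for p in PERIODS]
    for p, s, e in intervals:
        if e < s:
            raise ValueError(f"event {p}: end {e} before start {s}")
    bad = []
    for i, (pa, sa, ea) in enumerate(intervals):
        for pb, sb, eb in intervals[i + 1 :]:
            if max(sa, sb) < min(ea, eb):
                bad.append((pa, pb))
    if bad:
        raise ValueError(f"overlapping event intervals: {bad}")
    order = [events[p][0] for p in PERIODS]
    if not order[0] <= order[1] <= order[2]:
        raise ValueError("events must be ordered control, supply, feeding")


def split_session(
    profile: SpeedProfile, events: dict
) -> tuple[dict[str, np.ndarray], dict[str, int]]:
    """Assign every frame to control / supply / feeding / out-of-window.

    Returns boolean masks over frames and the frame counts per class.
    Supply frames belong to neither analysis segment; the four masks
    partition the recording exactly.
    """
    _check_events(events)
    t = profile.time_s
    masks = {}
    for p in PERIODS:
        s, e = events[p]
        masks[p] = (t >= s) & (t < e)
    masks["out"] = ~(masks["control"] | masks["supply"] | masks["feeding"])
    counts = {k: int(v.sum()) for k, v in masks.items()}
    counts["total"] = profile.n_frames
    return masks, counts


def summarize_session(
    session: FeedingSession, q: float = 0.95
) -> dict[str, KinematicsSummary]:
    """Per-period kinematic summaries of one session.

    Control and feeding segments are summarized with the shared
    mean / robust-maximum convention; the supply interval is excluded
    entirely, so any disturbance speed recorded there cannot influence
    the result.
    """
    masks, _ = split_session(session.profile, session.events)
    out = {}
    for period in ("control", "feeding"):
        if not (masks[period] & session.profile.valid).any():
            raise ValueError(f"segment {period!r} is empty for fish {session.fish_id}")
        out[period] = summarize_kinematics(
            session.profile, subset=masks[period], q=q, segment=period
        )
    return out


def build_feeding_table(sessions: list[FeedingSession], q: float = 0.95) -> pd.DataFrame:
    """Long-format per-period summary table over many sessions.

    One row per fish x age x period, with raw summaries and their
    natural-log transforms side by side (the transformed columns feed
    the downstream mixed models; raw mm/s units stay canonical).
    Duplicate (fish, age, period) combinations are an error; missing
    sessions are simply absent and logged.
    """
    if not sessions:
        raise ValueError("at least one session is required")
    rows = []
    for ses in sessions:
        sums = summarize_session(ses, q=q)
        for period, s in sums.items():
            rows.append(
                {
                    "fish_id": ses.fish_id,
                    "age_days": ses.age_days,
                    "treatment": ses.treatment,
                    "day": ses.day,
                    "dish_position": ses.dish_position,
                    "period": period,
                    "v_mean": s.v_mean,
                    "v_max": s.v_max,
                    "a_mean": s.a_mean,
                    "a_max": s.a_max,
                    "n_frames": s.n_frames,
                    "q": s.q,
                }
            )
    table = pd.DataFrame(rows)
    dup = table.duplicated(subset=["fish_id", "age_days", "period"])
    if dup.any():
        offenders = table.loc[dup, ["fish_id", "age_days", "period"]]
        raise ValueError(f"duplicate (fish, age, period) rows:\n{offenders}")
    expected = len({s.fish_id for s in sessions}) * len(AGES) * 2
    if len(table) < expected:
        logger.info(
            "feeding table has %d rows; a complete fish x age x period grid "
            "would have %d",
            len(table),
            expected,
        )
    for col in ("v_mean", "v_max", "a_mean", "a_max"):
        with np.errstate(divide="ignore"):
            table[f"ln_{col}"] = np.log(table[col].to_numpy())
    return table
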