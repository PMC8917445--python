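"""Synthetic cohort, trial and session generator.

The raw recordings behind the original maternal food-restriction study
were never deposited, so every downstream stage is validated against
data generated here with known ground truth:

* startle trials — a mixture of responders (a fast speed pulse peaking
  inside the 0-0.157 s response interval, ~150-250 mm/s) and
  non-responders (slow residual motion), matching the bimodal pooled
  speed histogram the valley threshold relies on;
* feeding sessions — a 5-min no-food control period, a short food-supply
  interval contaminated with experimenter disturbance, and a 5-min
  feeding period with more frequent and (with age) faster swim bouts;
* offspring cohorts — dry mass and (square-root-scale) body fat
  following a linear model in treatment, experimental day, day^2, age
  and their interactions, with maternal random intercepts and a
  day-dependent alive probability.

Randomness uses one root seed per generator call; per-entity substreams
are spawned deterministically from it, so identical parameters always
reproduce identical data, and each fish's data does not depend on how
many other fish are generated after it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .faststart import DEFAULT_DT, RESPONSE_WINDOW, FastStartTrial
from .feeding import FeedingSession
from .kinematics import SpeedProfile
from .render import RenderParams, render_frames  # re-exported: rendering is
# part of the generator's contract
from .tracking import FASTSTART_DISH_MM, Track

logger = logging.getLogger(__name__)

__all__ = [
    "NormalSpec",
    "FastStartSimParams",
    "FeedingSimParams",
    "Betas",
    "CohortSimParams",
    "RenderParams",
    "simulate_fast_start_trials",
    "simulate_feeding_session",
    "simulate_cohort",
    "render_frames",
]


@dataclass(frozen=True)
class NormalSpec:
    """Normal distribution spec (mean, sd), optionally clipped at zero."""

    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError(f"sd must be non-negative, got {self.sd}")

    def draw(self, rng: np.random.Generator, size=None, floor: float | None = 0.0):
        x = rng.normal(self.mean, self.sd, size=size)
        if floor is not None:
            x = np.maximum(x, floor)
        return x


def _gamma_pulse(
    t: np.ndarray, peak: float, latency: float, rise: float, decay: float
) -> np.ndarray:
    """Single-peaked asymmetric speed pulse.

    Rises over ``rise`` seconds to ``peak`` and relaxes with time
    constant ``decay``; shape ``(tau/rise * exp(1 - tau/rise))**s`` with
    ``s = rise/decay`` gives a fast rise and slower decay when
    ``decay > rise``, reproducing the single-peaked escape profiles.
    """
    tau = np.asarray(t, dtype=float) - latency
    s = rise / decay
    x = np.where(tau > 0, tau / rise, 0.0)
    with np.errstate(invalid="ignore"):
        v = np.where(x > 0, (x * np.exp(1.0 - x)) ** s, 0.0)
    return peak * v


def _integrate_positions(
    speed: np.ndarray,
    dt: float,
    start: np.ndarray,
    heading0: float,
    turn_sd: float,
    radius: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, int]:
    """Integrate a speed profile along a wandering heading inside a disc.

    Step ``i`` has length ``speed[i] * dt``. A step that would cross the
    wall is split at the intersection and the heading specularly
    reflected, so the emitted path length equals the speed integral
    exactly. Returns (n, 2) positions and the reflection count.
    """
    n = len(speed)
    pos = np.empty((n, 2))
    pos[0] = start
    theta = heading0
    n_reflect = 0
    for i in range(1, n):
        theta += rng.normal(0.0, turn_sd)
        remaining = speed[i - 1] * dt
        p = pos[i - 1].copy()
        d = np.array([np.cos(theta), np.sin(theta)])
        guard = 0
        while remaining > 1e-12 and guard < 8:
            nxt = p + remaining * d
            if np.hypot(*nxt) <= radius:
                p = nxt
                break
            # solve |p + s*d| = radius for the wall hit 0 <= s <= remaining
            b = float(np.dot(p, d))
            c = float(np.dot(p, p)) - radius**2
            disc = max(b * b - c, 0.0)
            s_hit = -b + np.sqrt(disc)
            s_hit = min(max(s_hit, 0.0), remaining)
            p = p + s_hit * d
            normal = p / max(np.hypot(*p), 1e-12)
            d = d - 2.0 * float(np.dot(d, normal)) * normal
            theta = float(np.arctan2(d[1], d[0]))
            # nudge off the wall to avoid re-hitting it at s = 0
            p = p - 1e-9 * normal
            remaining -= s_hit
            n_reflect += 1
            guard += 1
        pos[i] = p
    return pos, n_reflect


@dataclass(frozen=True)
class FastStartSimParams:
    """Conditions of a simulated startle experiment.

    Defaults emulate the original cohort: three trials per fish, about
    one third of trials showing a genuine response, responder peak
    speeds far above the 60 mm/s valley and non-responders far below
    it, and pulses peaking inside the 0.103-0.120 s window where the
    7-frame classification rule looks.
    """

    n_fish: int
    trials_per_fish: int = 3
    responder_fraction: float = 1.0 / 3.0
    responder_peak_speed: NormalSpec = NormalSpec(180.0, 40.0)
    nonresponder_peak_speed: NormalSpec = NormalSpec(15.0, 5.0)
    latency: NormalSpec = NormalSpec(0.085, 0.008)
    pulse_rise_s: float = 0.020
    pulse_decay_s: float = 0.035
    nonresponder_rise_s: float = 0.080
    nonresponder_decay_s: float = 0.150
    #: residual slow-drift speed level (mm/s); real centroid tracks never
    #: measure exactly zero speed, and this floor forms the low mode of
    #: the pooled histogram
    baseline_speed: NormalSpec = NormalSpec(8.0, 3.0)
    frame_rate: float = 1.0 / DEFAULT_DT
    duration: float = 0.25
    dish_diameter_mm: float = FASTSTART_DISH_MM
    start_radius_frac: float = 0.3
    turn_sd_rad: float = 0.05
    #: closest the centroid gets to the wall: half a ~7 mm body plus
    #: clearance, so rendered silhouettes stay fully inside the dish
    wall_margin_mm: float = 4.0
    trial_completion_prob: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.responder_fraction <= 1.0:
            raise ValueError("responder_fraction must lie in [0, 1]")
        if self.responder_peak_speed.mean <= self.nonresponder_peak_speed.mean:
            raise ValueError("responder mean speed must exceed non-responder mean")
        if self.duration < RESPONSE_WINDOW[1]:
            raise ValueError(
                f"duration must cover the response window (>= {RESPONSE_WINDOW[1]} s)"
            )
        if not 1 <= self.trials_per_fish <= 3:
            raise ValueError("trials_per_fish must be 1..3")
        if not 0.0 <= self.trial_completion_prob <= 1.0:
            raise ValueError("trial_completion_prob must lie in [0, 1]")


def simulate_fast_start_trials(params: FastStartSimParams) -> list[FastStartTrial]:
    """Generate startle trials with latent responder labels.

    Each trial carries its true label (``trial.truth``), the drawn peak
    speed and latency (``trial.meta``), a full :class:`Track` confined
    to the dish (specular wall reflections, logged per trial), and the
    noise-free :class:`SpeedProfile` whose integral equals the emitted
    path length.
    """
    dt = 1.0 / params.frame_rate
    n_frames = int(round(params.duration / dt)) + 1
    t = np.arange(n_frames) * dt
    radius = params.dish_diameter_mm / 2.0 - params.wall_margin_mm
    root = np.random.SeedSequence(params.seed)
    fish_streams = root.spawn(params.n_fish)
    trials: list[FastStartTrial] = []
    for i, fs in enumerate(fish_streams):
        fish_id = f"f{i:03d}"
        trial_streams = fs.spawn(params.trials_per_fish)
        for j in range(params.trials_per_fish):
            rng = np.random.default_rng(trial_streams[j])
            completed = j == 0 or rng.random() < params.trial_completion_prob
            if not completed:
                break  # fish not re-tested; later trials never happen
            is_responder = bool(rng.random() < params.responder_fraction)
            if is_responder:
                peak = float(params.responder_peak_speed.draw(rng))
                rise, decay = params.pulse_rise_s, params.pulse_decay_s
            else:
                peak = float(params.nonresponder_peak_speed.draw(rng))
                rise, decay = params.nonresponder_rise_s, params.nonresponder_decay_s
            latency = float(max(params.latency.draw(rng, floor=None), 0.0))
            baseline = float(params.baseline_speed.draw(rng))
            # the pulse dominates wherever it exceeds the drift floor, so
            # the trial's true maximum speed is the drawn peak itself
            speed = np.maximum(_gamma_pulse(t, peak, latency, rise, decay), baseline)
            start_r = radius * params.start_radius_frac * np.sqrt(rng.random())
            start_phi = rng.uniform(0, 2 * np.pi)
            start = start_r * np.array([np.cos(start_phi), np.sin(start_phi)])
            pos, n_reflect = _integrate_positions(
                speed, dt, start, rng.uniform(0, 2 * np.pi),
                params.turn_sd_rad, radius, rng,
            )
            if n_reflect:
                logger.info(
                    "trial %s/%d: heading reflected at the dish wall %d time(s)",
                    fish_id, j + 1, n_reflect,
                )
            accel = np.gradient(speed, dt)
            track = Track(
                fish_id=fish_id,
                dish_id=f"pos{i % 5}",
                frames=np.arange(n_frames),
                time_s=t,
                x_mm=pos[:, 0],
                y_mm=pos[:, 1],
                valid=np.ones(n_frames, dtype=bool),
            )
            profile = SpeedProfile(
                fish_id=fish_id,
                time_s=t,
                speed=speed,
                accel=accel,
                valid=np.ones(n_frames, dtype=bool),
                smoothing={"source": "generator"},
            )
            trials.append(
                FastStartTrial(
                    fish_id=fish_id,
                    trial_index=j + 1,
                    profile=profile,
                    dish_position=track.dish_id,
                    truth=is_responder,
                    track=track,
                    meta={
                        "true_peak_speed": max(peak, baseline),
                        "baseline_speed": baseline,
                        "latency_s": latency,
                        "n_reflections": n_reflect,
                        "path_length_mm": float(
                            np.hypot(*np.diff(pos, axis=0).T).sum()
                        ),
                        "speed_integral_mm": float(speed[:-1].sum() * dt),
                    },
                )
            )
    return trials


#: default feeding-bout peak-speed specs per (treatment, age): bout speed
#: increases with age, more strongly under high maternal food
DEFAULT_BOUT_SPEEDS = {
    ("LF", 0): NormalSpec(40.0, 10.0),
    ("LF", 2): NormalSpec(48.0, 11.0),
    ("LF", 7): NormalSpec(55.0, 12.0),
    ("HF", 0): NormalSpec(40.0, 10.0),
    ("HF", 2): NormalSpec(55.0, 12.0),
    ("HF", 7): NormalSpec(72.0, 15.0),
}


@dataclass(frozen=True)
class FeedingSimParams:
    """Conditions of one simulated feeding session.

    Swimming is modelled as discrete bouts: Poisson arrivals per segment
    with single-peaked speed pulses. Food raises the bout rate; bout
    peak speed depends on (treatment, age). The supply interval carries
    large erratic experimenter-disturbance speeds that downstream
    analysis must excise.
    """

    fish_id: str = "f000"
    treatment: str = "HF"
    age: int = 7
    day: int = 30
    control_duration: float = 300.0
    feeding_duration: float = 300.0
    supply_gap: float = 20.0
    bout_rate_control: float = 0.05
    bout_rate_feeding: float = 0.25
    bout_speeds: dict = field(default_factory=lambda: dict(DEFAULT_BOUT_SPEEDS))
    control_bout_speed: NormalSpec = NormalSpec(30.0, 8.0)
    bout_rise_s: float = 0.15
    bout_decay_s: float = 0.30
    disturbance_speed: NormalSpec = NormalSpec(150.0, 50.0)
    frame_rate: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.control_duration <= 0 or self.feeding_duration <= 0:
            raise ValueError("segment durations must be positive")
        if self.supply_gap < 0:
            raise ValueError("supply_gap must be non-negative")
        if self.bout_rate_control < 0 or self.bout_rate_feeding < 0:
            raise ValueError("bout rates must be non-negative")
        if self.age not in (0, 2, 7):
            raise ValueError("age must be 0, 2 or 7 days")


def simulate_feeding_session(params: FeedingSimParams) -> FeedingSession:
    """Generate one feeding session with ground-truth bout list.

    ``session.truth`` records the bout table and the per-segment mean of
    the clean (disturbance-free) speed signal, the quantity the
    analysis chain should recover.
    """
    dt = 1.0 / params.frame_rate
    cd, gap, fd = params.control_duration, params.supply_gap, params.feeding_duration
    total = cd + gap + fd
    n = int(round(total / dt))
    t = np.arange(n) * dt
    events = {
        "control": (0.0, cd),
        "supply": (cd, cd + gap),
        "feeding": (cd + gap, total),
    }
    root = np.random.SeedSequence(params.seed)
    rng_bouts, rng_dist = (np.random.default_rng(s) for s in root.spawn(2))
    clean = np.zeros(n)
    bout_rows = []
    segs = [
        ("control", 0.0, cd, params.bout_rate_control, params.control_bout_speed),
        (
            "feeding",
            cd + gap,
            total,
            params.bout_rate_feeding,
            params.bout_speeds[(params.treatment, params.age)],
        ),
    ]
    for name, s0, s1, rate, speed_spec in segs:
        n_bouts = rng_bouts.poisson(rate * (s1 - s0))
        starts = np.sort(rng_bouts.uniform(s0, s1, size=n_bouts))
        peaks = speed_spec.draw(rng_bouts, size=n_bouts)
        for b0, pk in zip(starts, peaks):
            clean += _gamma_pulse(t, pk, b0, params.bout_rise_s, params.bout_decay_s)
            bout_rows.append({"segment": name, "t_start_s": b0, "peak_speed": pk})
    speed = clean.copy()
    in_gap = (t >= cd) & (t < cd + gap)
    if in_gap.any():
        speed[in_gap] += np.abs(
            params.disturbance_speed.draw(rng_dist, size=int(in_gap.sum()), floor=None)
        )
    accel = np.gradient(speed, dt)
    profile = SpeedProfile(
        fish_id=params.fish_id,
        time_s=t,
        speed=speed,
        accel=accel,
        valid=np.ones(n, dtype=bool),
        smoothing={"source": "generator"},
    )
    masks = {
        "control": (t >= 0) & (t < cd),
        "feeding": (t >= cd + gap) & (t < total),
    }
    truth = {
        "bouts": pd.DataFrame(bout_rows, columns=["segment", "t_start_s", "peak_speed"]),
        "control_mean": float(clean[masks["control"]].mean()),
        "feeding_mean": float(clean[masks["feeding"]].mean()),
    }
    return FeedingSession(
        fish_id=params.fish_id,
        age_days=params.age,
        treatment=params.treatment,
        day=params.day,
        profile=profile,
        events=events,
        truth=truth,
    )


@dataclass(frozen=True)
class Betas:
    """Fixed-effect coefficients of one trait (treatment coded LF=0/HF=1)."""

    intercept: float
    treatment: float = 0.0
    day: float = 0.0
    day2: float = 0.0
    age: float = 0.0
    treat_day: float = 0.0
    treat_age: float = 0.0

    def predict(self, treat: float, day: float, age: float) -> float:
        return (
            self.intercept
            + self.treatment * treat
            + self.day * day
            + self.day2 * day**2
            + self.age * age
            + self.treat_day * treat * day
            + self.treat_age * treat * age
        )


#: per-day dry-mass slopes reproduce the reported decline: -0.010 mg/day
#: for LF mothers, -0.003 mg/day for HF (treat_day = +0.007 with LF = 0)
DEFAULT_COHORT_BETAS = {
    "dry_mass": Betas(
        intercept=1.40, treatment=0.0, day=-0.010, day2=-2e-5,
        age=0.030, treat_day=0.007, treat_age=0.010,
    ),
    "sqrt_body_fat": Betas(
        intercept=0.55, treatment=0.0, day=-0.001, day2=0.0,
        age=0.010, treat_day=0.0005, treat_age=0.0,
    ),
}

#: twice-weekly offspring collection days across the 51-day experiment
DEFAULT_COLLECTION_DAYS = (1, 4, 8, 11, 15, 18, 22, 25, 29, 32, 36, 39, 43, 46, 50)


@dataclass(frozen=True)
class CohortSimParams:
    """Conditions of a simulated offspring cohort.

    Dry mass (mg) and body fat (generated on the square-root scale and
    squared) follow the linear model; lean mass is derived as
    ``dry_mass - body_fat`` so the trait additivity invariant holds by
    construction. The alive flag follows a day-dependent logit but does
    not censor traits.
    """

    #: the study housed one female per aquarium in 50 aquaria
    n_mothers: int = 50
    betas: dict = field(default_factory=lambda: dict(DEFAULT_COHORT_BETAS))
    sigma_mother: dict = field(
        default_factory=lambda: {"dry_mass": 0.06, "sqrt_body_fat": 0.02}
    )
    sigma_resid: dict = field(
        default_factory=lambda: {"dry_mass": 0.08, "sqrt_body_fat": 0.03}
    )
    collection_days: tuple = DEFAULT_COLLECTION_DAYS
    litter_prob: float = 0.7
    alive_intercept: float = 3.0
    alive_day_slope: float = -0.065
    food_rations_ul: dict = field(default_factory=lambda: {"LF": 25.0, "HF": 100.0})
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_mothers < 2 or self.n_mothers % 2:
            raise ValueError("n_mothers must be an even count >= 2")
        for d in (self.sigma_mother, self.sigma_resid):
            if any(v < 0 for v in d.values()):
                raise ValueError("variance components must be non-negative")
        if not all(1 <= d <= 51 for d in self.collection_days):
            raise ValueError("collection days must lie within 1..51")


def simulate_cohort(params: CohortSimParams) -> tuple[pd.DataFrame, dict]:
    """Generate a cohort trait table plus ground truth.

    Returns the records table (one offspring per row) and a truth dict
    holding the generating coefficients and the implied per-treatment
    dry-mass day slopes.
    """
    root = np.random.SeedSequence(params.seed)
    streams = root.spawn(params.n_mothers)
    traits = list(params.betas)
    rows = []
    for m, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        treatment = "LF" if m < params.n_mothers // 2 else "HF"
        tcode = float(treatment == "HF")
        u = {tr: rng.normal(0.0, params.sigma_mother[tr]) for tr in traits}
        for day in params.collection_days:
            if rng.random() >= params.litter_prob:
                continue
            age = 7 if rng.random() < 0.5 else 0
            vals = {}
            for tr in traits:
                mu = params.betas[tr].predict(tcode, float(day), float(age))
                vals[tr] = mu + u[tr] + rng.normal(0.0, params.sigma_resid[tr])
            dry = vals["dry_mass"]
            fat = max(vals.get("sqrt_body_fat", 0.0), 0.0) ** 2
            if dry <= 0:
                logger.warning("clipping non-positive dry mass draw to 0.01 mg")
                dry = 0.01
            fat = min(fat, dry)
            alive_logit = params.alive_intercept + params.alive_day_slope * day
            alive = bool(rng.random() < 1.0 / (1.0 + np.exp(-alive_logit)))
            rows.append(
                {
                    "offspring_id": f"o{m:03d}d{day:02d}",
                    "mother_id": f"m{m:03d}",
                    "treatment": treatment,
                    "experimental_day": day,
                    "age_days": age,
                    "dry_mass": dry,
                    "lean_mass": dry - fat,
                    "body_fat": fat,
                    "alive": alive,
                    "food_ration_ul": params.food_rations_ul[treatment],
                }
            )
    records = pd.DataFrame(rows)
    b = params.betas["dry_mass"]
    truth = {
        "betas": dict(params.betas),
        "dry_mass_slope_lf": b.day,
        "dry_mass_slope_hf": b.day + b.treat_day,
        "interaction_lf_minus_hf": -b.treat_day,
        "sigma_mother": dict(params.sigma_mother),
        "sigma_resid": dict(params.sigma_resid),
    }
    return records, truth
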