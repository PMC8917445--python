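"""Cohort trait tables: transforms, model design, and slope recovery.

Offspring of low-food (LF) and high-food (HF) mothers are collected
over a 51-day experiment and measured at age 0 or 7 days for dry mass,
lean dry mass and body fat. The downstream mixed models (fitted in
external software) use fixed effects for treatment, experimental day,
day^2, age, treatment x day and treatment x age, plus random intercepts
for mother (and, where applicable, offspring, dish position and trial);
body fat enters on the square-root scale and kinematic summaries on the
natural-log scale. This module carries those transforms and the design
matrix, and provides a transparent desk-scale estimator — within-mother
least squares with a cluster bootstrap over mothers — to test whether
generated treatment x day effects are recoverable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TREATMENT_CODE = {"LF": 0, "HF": 1}
DAY_RANGE = (1, 51)

REQUIRED_COLUMNS = (
    "offspring_id",
    "mother_id",
    "treatment",
    "experimental_day",
    "age_days",
    "dry_mass",
    "lean_mass",
    "body_fat",
    "alive",
)


@dataclass(frozen=True)
class CohortRecord:
    """One offspring measurement (masses in mg)."""

    offspring_id: str
    mother_id: str
    treatment: str
    experimental_day: int
    age_days: int
    dry_mass: float
    lean_mass: float
    body_fat: float
    alive: bool

    def __post_init__(self) -> None:
        if self.treatment not in TREATMENT_CODE:
            raise ValueError(f"unknown treatment {self.treatment!r}")
        if not DAY_RANGE[0] <= self.experimental_day <= DAY_RANGE[1]:
            raise ValueError(f"experimental_day outside {DAY_RANGE}")
        if self.age_days not in (0, 7):
            raise ValueError("age_days must be 0 or 7")
        if self.body_fat < -1e-9 or self.lean_mass > self.dry_mass + 1e-9:
            raise ValueError("need 0 <= body_fat and lean_mass <= dry_mass")
        if abs(self.dry_mass - self.lean_mass - self.body_fat) > 1e-6:
            raise ValueError("body_fat must equal dry_mass - lean_mass")


def validate_cohort(records: pd.DataFrame) -> pd.DataFrame:
    """Check a cohort table against the record invariants."""
    missing = [c for c in REQUIRED_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"cohort table missing columns: {missing}")
    for _, row in records.iterrows():
        CohortRecord(**{c: row[c] for c in REQUIRED_COLUMNS})
    return records


def apply_transforms(table: pd.DataFrame) -> pd.DataFrame:
    """Add the model-scale transform columns.

    ``body_fat`` gains ``sqrt_body_fat``; each kinematic summary column
    (v_mean, v_max, a_mean, a_max) gains an ``ln_`` twin. Originals are
    retained. Rows with a negative body fat or a non-positive value
    under a log transform are excluded, with the count logged.
    """
    out = table.copy()
    n0 = len(out)
    if "body_fat" in out.columns:
        bad = out["body_fat"] < 0
        if bad.any():
            logger.warning("excluding %d rows with negative body_fat", int(bad.sum()))
            out = out[~bad].copy()
        out["sqrt_body_fat"] = np.sqrt(out["body_fat"])
    kin = [c for c in ("v_mean", "v_max", "a_mean", "a_max") if c in out.columns]
    if kin:
        bad = np.zeros(len(out), dtype=bool)
        for c in kin:
            bad |= out[c].to_numpy() <= 0
        if bad.any():
            logger.warning(
                "excluding %d rows with non-positive kinematics under ln", int(bad.sum())
            )
            out = out[~bad].copy()
        for c in kin:
            out[f"ln_{c}"] = np.log(out[c].to_numpy())
    n_dropped = n0 - len(out)
    out.attrs["n_excluded"] = n_dropped
    return out


def build_design(records: pd.DataFrame, centre_day: float | None = None) -> pd.DataFrame:
    """Fixed-effect design table for the offspring trait models.

    Coding (documented here and in the export dictionary): treatment
    LF = 0 / HF = 1; age in days; ``day2 = day**2`` on the (optionally
    centred) day scale; interactions are products of the coded columns.
    Grouping columns (mother, offspring, and dish position / trial when
    present) are carried through for the random-intercept structure.
    One row per input record, never silently dropped.
    """
    unknown = set(records["treatment"]) - set(TREATMENT_CODE)
    if unknown:
        raise ValueError(f"unknown treatment levels: {sorted(unknown)}")
    day = records["experimental_day"].to_numpy(dtype=float)
    if centre_day is not None:
        day = day - centre_day
    treat = records["treatment"].map(TREATMENT_CODE).to_numpy(dtype=float)
    age = records["age_days"].to_numpy(dtype=float)
    design = pd.DataFrame(
        {
            "intercept": np.ones(len(records)),
            "treatment": treat,
            "day": day,
            "day2": day**2,
            "age": age,
            "treat_day": treat * day,
            "treat_age": treat * age,
        },
        index=records.index,
    )
    if "alive" in records.columns:
        design["alive"] = records["alive"].astype(int).to_numpy()
    for g in ("mother_id", "offspring_id", "dish_position", "trial_index"):
        if g in records.columns:
            design[g] = records[g].to_numpy()
    assert len(design) == len(records)
    return design


@dataclass(frozen=True)
class SlopeEstimate:
    """Per-treatment day slopes of a trait with cluster-bootstrap CIs.

    ``interaction`` is the LF - HF slope contrast, the desk-scale
    analogue of the treatment x day fixed effect.
    """

    trait: str
    slope_lf: float
    ci_lf: tuple[float, float]
    slope_hf: float
    ci_hf: tuple[float, float]
    interaction: float
    ci_interaction: tuple[float, float]
    n_mothers: dict
    n_boot: int
    seed: int

    def __post_init__(self) -> None:
        for point, (lo, hi) in (
            (self.slope_lf, self.ci_lf),
            (self.slope_hf, self.ci_hf),
            (self.interaction, self.ci_interaction),
        ):
            if not lo <= point <= hi:
                raise ValueError("CI must bracket the point estimate")


def _mother_grams(
    df: pd.DataFrame, trait: str, covariates: tuple[str, ...]
) -> tuple[np.ndarray, np.ndarray]:
    """Per-mother normal-equation blocks on mother-mean-centred data.

    Demeaning trait and covariates within each mother removes the
    maternal intercept exactly, so the slope reflects within-mother
    variation across experimental days only. Because each mother's
    block is demeaned within itself, the blocks are invariant under
    cluster resampling: a bootstrap replicate's normal equations are
    just the sum of its drawn mothers' blocks.

    Returns ``A`` of shape (m, k, k) and ``b`` of shape (m, k), one
    block per mother.
    """
    cols = [trait, *covariates]
    centred = df[cols].astype(float) - df.groupby("mother_id")[cols].transform("mean")
    X = centred[list(covariates)].to_numpy()
    y = centred[trait].to_numpy()
    codes = pd.factorize(df["mother_id"])[0]
    m, k = codes.max() + 1, X.shape[1]
    A = np.zeros((m, k, k))
    b = np.zeros((m, k))
    for g in range(m):
        sel = codes == g
        Xg = X[sel]
        A[g] = Xg.T @ Xg
        b[g] = Xg.T @ y[sel]
    return A, b


def _solve_day_slope(A_sum: np.ndarray, b_sum: np.ndarray) -> float:
    """Day coefficient from summed normal equations; drops covariates
    with no within-mother variation (zero diagonal) instead of failing."""
    if A_sum[0, 0] <= 0:
        raise ValueError(
            "degenerate design: experimental day does not vary within mothers"
        )
    keep = np.flatnonzero(np.diag(A_sum) > 1e-12)
    sol = np.linalg.solve(A_sum[np.ix_(keep, keep)], b_sum[keep])
    beta = np.zeros(len(b_sum))
    beta[keep] = sol
    return float(beta[0])


def estimate_treatment_slopes(
    records: pd.DataFrame,
    trait: str,
    n_boot: int = 1000,
    seed: int = 0,
    covariates: tuple[str, ...] = ("day", "day2", "age"),
) -> SlopeEstimate:
    """Per-treatment day slope of a trait with cluster-bootstrap CIs.

    For each treatment arm, the trait is regressed on experimental day
    (with day^2 and age as covariates) after mother-mean centring; the
    mother is the top-level cluster, so uncertainty comes from
    resampling mothers with replacement and percentile intervals. This
    is a transparent stand-in for the full mixed model, sufficient to
    check sign and rough magnitude of the treatment x day effect.
    """
    df = records.copy()
    df["day"] = df["experimental_day"].astype(float)
    df["day2"] = df["day"] ** 2
    df["age"] = df["age_days"].astype(float)
    for arm in ("LF", "HF"):
        n_m = df.loc[df["treatment"] == arm, "mother_id"].nunique()
        if n_m < 5:
            raise ValueError(f"need >= 5 mothers per treatment, {arm} has {n_m}")
    point = {}
    grams = {}
    for arm in ("LF", "HF"):
        sub = df[df["treatment"] == arm]
        grams[arm] = _mother_grams(sub, trait, covariates)
        A, b = grams[arm]
        point[arm] = _solve_day_slope(A.sum(axis=0), b.sum(axis=0))
    rng = np.random.default_rng(seed)
    boot = {"LF": np.empty(n_boot), "HF": np.empty(n_boot)}
    for rep in range(n_boot):
        for arm in ("LF", "HF"):
            A, b = grams[arm]
            draw = rng.integers(0, len(A), size=len(A))
            boot[arm][rep] = _solve_day_slope(A[draw].sum(axis=0), b[draw].sum(axis=0))
    inter = boot["LF"] - boot["HF"]

    def ci(a: np.ndarray, point_val: float) -> tuple[float, float]:
        lo, hi = np.percentile(a, [2.5, 97.5])
        return (min(float(lo), point_val), max(float(hi), point_val))

    return SlopeEstimate(
        trait=trait,
        slope_lf=point["LF"],
        ci_lf=ci(boot["LF"], point["LF"]),
        slope_hf=point["HF"],
        ci_hf=ci(boot["HF"], point["HF"]),
        interaction=point["LF"] - point["HF"],
        ci_interaction=ci(inter, point["LF"] - point["HF"]),
        n_mothers={
            arm: int(df.loc[df["treatment"] == arm, "mother_id"].nunique())
            for arm in ("LF", "HF")
        },
        n_boot=n_boot,
        seed=seed,
    )


COLUMN_DICTIONARY = {
    "fish_id": ("identifier", "fish identity"),
    "offspring_id": ("identifier", "offspring identity"),
    "mother_id": ("identifier", "maternal identity (random-intercept cluster)"),
    "treatment": ("LF/HF", "maternal food treatment (LF=25 ul, HF=100 ul ration)"),
    "experimental_day": ("day 1-51", "day of the experiment the offspring was born"),
    "day": ("day", "experimental day as a numeric covariate"),
    "day2": ("day^2", "quadratic day term"),
    "age_days": ("days", "offspring age at measurement"),
    "age": ("days", "offspring age as a numeric covariate"),
    "alive": ("0/1", "offspring found alive at collection"),
    "dry_mass": ("mg", "offspring dry mass"),
    "lean_mass": ("mg", "lean dry mass = dry_mass - body_fat"),
    "body_fat": ("mg", "extractable body fat"),
    "sqrt_body_fat": ("sqrt(mg)", "square-root transformed body fat (model scale)"),
    "period": ("control/feeding", "feeding-trial segment"),
    "dish_position": ("label", "Petri dish position on the plate"),
    "trial_index": ("1-3", "startle trial number"),
    "v_mean": ("mm/s", "mean speed over the segment"),
    "v_max": ("mm/s", "robust maximum speed (mean above 95% quantile)"),
    "a_mean": ("mm/s^2", "mean acceleration magnitude"),
    "a_max": ("mm/s^2", "robust maximum acceleration"),
    "n_frames": ("count", "valid frames used"),
    "q": ("probability", "quantile used for the robust maximum"),
}


def export_tidy(tables: dict[str, pd.DataFrame], destination: str | Path) -> list[Path]:
    """Write analysis-ready CSVs plus a data dictionary.

    Each table becomes ``<name>.csv`` (UTF-8, one observation per row);
    ``data_dictionary.txt`` lists every column with its unit and
    meaning, so the files can be loaded directly into external
    mixed-model software. Returns the written paths.
    """
    dest = Path(destination)
    dest.mkdir(parents=True, exist_ok=True)
    written = []
    dict_lines = []
    for name, table in tables.items():
        path = dest / f"{name}.csv"
        table.to_csv(path, index=False, encoding="utf-8")
        if table.empty:
            logger.warning("table %s is empty; header-only CSV written", name)
        written.append(path)
        dict_lines.append(f"# {name}.csv ({len(table)} rows)")
        for col in table.columns:
            base = col[3:] if col.startswith("ln_") else col
            unit, desc = COLUMN_DICTIONARY.get(base, ("unspecified", "unspecified"))
            if col.startswith("ln_"):
                unit, desc = f"ln({unit})", f"natural log of: {desc}"
            dict_lines.append(f"{col}: [{unit}] {desc}")
        dict_lines.append("")
    dict_path = dest / "data_dictionary.txt"
    dict_path.write_text("\n".join(dict_lines), encoding="utf-8")
    written.append(dict_path)
    return written
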