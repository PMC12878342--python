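"""Synthetic longitudinal cohort generation.

Parameter vectors are drawn from a truncated multivariate normal whose
moments are configurable per group; trajectories are forward-evaluated with
the core model and observed on a jittered well-baby/school-style schedule
with instrument rounding (0.5 cm for infant length, 0.1 cm for standing
height).  A truth table of the generating parameters accompanies every
cohort so recovery can be tested end to end.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import PARAM_NAMES, QEPSParams, ShapeConstants, total_height
from .fitting import (
    INFANCY_CUTOFF_YEARS,
    GrowthRecord,
    Measurement,
    default_measurement_sd,
)

__all__ = [
    "CohortSpec",
    "generate_cohort",
    "preset_specs",
    "get_preset",
    "DEFAULT_SCHEDULE",
]


def _default_schedule() -> tuple[float, ...]:
    # Birth, well-baby visits at 2/4/6/9/12/18/24 months, annual checks from
    # 3 to 18 y, a school measurement at 17.5 y, and follow-up visits at
    # 19/20 y for those still growing.
    months = (2, 4, 6, 9, 12, 18, 24)
    ages = [0.0] + [m / 12.0 for m in months] + [float(y) for y in range(3, 19)]
    ages += [17.5, 19.0, 20.0]
    return tuple(sorted(ages))


DEFAULT_SCHEDULE = _default_schedule()

_DEFAULT_CORR = np.eye(6)
# Modest positive coupling of the two prepubertal amplitudes, and earlier
# puberty going with a larger spurt; all other pairs uncorrelated.
_DEFAULT_CORR[0, 1] = _DEFAULT_CORR[1, 0] = 0.3
_DEFAULT_CORR[2, 5] = _DEFAULT_CORR[5, 2] = -0.3


@dataclass(frozen=True)
class CohortSpec:
    """Generator configuration for one synthetic group.

    ``param_means``/``param_sds`` are ordered as
    (e_heightscale_cm, q_heightscale_cm, p_heightscale_cm,
    e_timescale, p_timescale, age_p50_years).
    """

    n: int
    group: str
    param_means: tuple[float, ...]
    param_sds: tuple[float, ...]
    correlation: tuple[tuple[float, ...], ...] = tuple(
        tuple(row) for row in _DEFAULT_CORR
    )
    schedule_ages: tuple[float, ...] = DEFAULT_SCHEDULE
    schedule_jitter_sd_years: float = 0.05
    round_infancy_cm: float = 0.5
    round_later_cm: float = 0.1
    ga_mean_weeks: float = 39.8
    ga_sd_weeks: float = 1.2
    ga_min_weeks: float = 37.0
    ga_max_weeks: float = 42.0
    p_missing_ga: float = 0.0
    mother_mean_cm: float = 166.8
    mother_sd_cm: float = 6.2
    father_mean_cm: float = 179.5
    father_sd_cm: float = 6.7
    p_missing_parents: float = 0.0
    birth_weight_mean_g: float = 3517.0
    birth_weight_sd_g: float = 486.0
    stop_mode: str = "hard_cap"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("n must be positive")
        if len(self.param_means) != 6 or len(self.param_sds) != 6:
            raise ValueError("param_means and param_sds must have 6 entries")
        if any(s <= 0 for s in self.param_sds):
            raise ValueError("param_sds must be positive")
        corr = np.asarray(self.correlation, dtype=float)
        if corr.shape != (6, 6):
            raise ValueError("correlation must be 6x6")
        if not np.allclose(corr, corr.T):
            raise ValueError("correlation must be symmetric")
        if np.min(np.linalg.eigvalsh(corr)) <= 0:
            raise ValueError("correlation matrix must be positive definite")
        ages = self.schedule_ages
        if any(b <= a for a, b in zip(ages, ages[1:])):
            raise ValueError("schedule ages must strictly increase")

    @property
    def covariance(self) -> np.ndarray:
        d = np.diag(self.param_sds)
        return d @ np.asarray(self.correlation) @ d


def _valid_theta(theta: np.ndarray) -> np.ndarray:
    """Row mask of draws satisfying the parameter invariants."""
    e, q, p, ets, pts, p50 = theta.T
    return (
        (e > 0)
        & (q > 0)
        & (p > 0)
        & (ets > 0.4)
        & (ets < 2.5)
        & (pts > 0.4)
        & (pts < 2.5)
        & (p50 > 8.0)
        & (p50 < 20.0)
    )


def _draw_parameters(spec: CohortSpec, rng: np.random.Generator) -> np.ndarray:
    """Truncated multivariate normal: resample rows until invariants hold."""
    mean = np.asarray(spec.param_means)
    cov = spec.covariance
    out = np.empty((spec.n, 6))
    filled = 0
    for _ in range(1000):
        need = spec.n - filled
        draw = rng.multivariate_normal(mean, cov, size=max(need, 8))
        draw = draw[_valid_theta(draw)][:need]
        out[filled : filled + len(draw)] = draw
        filled += len(draw)
        if filled == spec.n:
            return out
    raise ValueError("spec is infeasible: truncation rejects nearly all draws")


def _round_to(values: np.ndarray, step: float) -> np.ndarray:
    if step <= 0:
        return values
    return np.round(values / step) * step


def _source_for(age: float) -> str:
    if age == 0.0:
        return "birth"
    if age < 3.0:
        return "well_baby"
    if age < 18.0:
        return "school"
    return "clinic"


def generate_cohort(
    spec: CohortSpec, seed: int | None = None
) -> tuple[list[GrowthRecord], pd.DataFrame]:
    """Generate a cohort of growth records plus the generating truth table.

    Fully reproducible: all randomness flows from ``seed`` (falling back to
    ``spec.seed``).
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    theta = _draw_parameters(spec, rng)

    ga = rng.normal(spec.ga_mean_weeks, spec.ga_sd_weeks, size=spec.n)
    ga = np.round(np.clip(ga, spec.ga_min_weeks, spec.ga_max_weeks))
    ga_missing = rng.random(spec.n) < spec.p_missing_ga

    mothers = rng.normal(spec.mother_mean_cm, spec.mother_sd_cm, size=spec.n)
    fathers = rng.normal(spec.father_mean_cm, spec.father_sd_cm, size=spec.n)
    parents_missing = rng.random(spec.n) < spec.p_missing_parents
    bw = rng.normal(spec.birth_weight_mean_g, spec.birth_weight_sd_g, size=spec.n)

    schedule = np.asarray(spec.schedule_ages)
    records: list[GrowthRecord] = []
    truth_rows = []
    for i in range(spec.n):
        rid = f"{spec.group}-{i:04d}"
        ga_i = None if ga_missing[i] else float(ga[i])
        shape = ShapeConstants.male(ga_i, stop_mode=spec.stop_mode)
        params = QEPSParams.from_array(theta[i], shape)

        jitter = rng.normal(0.0, spec.schedule_jitter_sd_years, size=len(schedule))
        jitter[schedule == 0.0] = 0.0  # birth length is taken at birth
        ages = np.maximum(schedule + jitter, 0.0)
        ages = np.sort(ages)
        keep = np.concatenate([[True], np.diff(ages) > 1e-6])
        ages = ages[keep]

        heights = total_height(ages, params)
        infant = ages < INFANCY_CUTOFF_YEARS
        heights = np.where(
            infant,
            _round_to(heights, spec.round_infancy_cm),
            _round_to(heights, spec.round_later_cm),
        )

        meas = [
            Measurement(
                float(a), float(h), _source_for(float(a)), default_measurement_sd(float(a))
            )
            for a, h in zip(ages, heights)
        ]
        birth_length = float(heights[0]) if ages[0] == 0.0 else None
        records.append(
            GrowthRecord(
                id=rid,
                measurements=meas,
                group=spec.group,
                sex="male",
                ga_weeks=ga_i,
                birth_weight_g=float(np.round(bw[i])),
                birth_length_cm=birth_length,
                mother_height_cm=None if parents_missing[i] else float(np.round(mothers[i], 1)),
                father_height_cm=None if parents_missing[i] else float(np.round(fathers[i], 1)),
            )
        )
        row = {"id": rid, "group": spec.group}
        row.update(zip(PARAM_NAMES, theta[i]))
        row["ga_weeks"] = ga_i
        row["t0_years"] = shape.t0_years
        truth_rows.append(row)

    return records, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# Presets: group moments of the two study populations.

_REFERENCE_MOMENTS = dict(
    means=(65.1, 104.1, 17.4, 1.01, 1.01, 13.8),
    sds=(2.9, 8.0, 3.6, 0.09, 0.05, 1.0),
)
# Total group with early-growth data (pubertal location/amplitude moments
# come from the adult-height subgroup).
_KS_MOMENTS = dict(
    means=(63.3, 110.9, 17.6, 0.96, 1.00, 13.3),
    sds=(3.5, 11.4, 4.5, 0.11, 0.05, 1.0),
)
# Subgroup followed to adult height.
_KS_PUBERTAL_MOMENTS = dict(
    means=(63.4, 111.5, 17.6, 0.96, 1.00, 13.3),
    sds=(3.5, 11.4, 4.5, 0.11, 0.05, 1.0),
)


def get_preset(name: str, n: int | None = None, seed: int = 0) -> CohortSpec:
    """Named generator presets with group moments and covariate settings."""
    if name == "reference":
        return CohortSpec(
            n=n if n is not None else 1174,
            group="reference",
            param_means=_REFERENCE_MOMENTS["means"],
            param_sds=_REFERENCE_MOMENTS["sds"],
            mother_mean_cm=166.8,
            mother_sd_cm=6.2,
            father_mean_cm=179.5,
            father_sd_cm=6.7,
            p_missing_parents=0.24,
            birth_weight_mean_g=3517.0,
            birth_weight_sd_g=486.0,
            p_missing_ga=0.0,
            seed=seed,
        )
    if name == "ks":
        return CohortSpec(
            n=n if n is not None else 55,
            group="ks",
            param_means=_KS_MOMENTS["means"],
            param_sds=_KS_MOMENTS["sds"],
            mother_mean_cm=167.9,
            mother_sd_cm=6.3,
            father_mean_cm=179.2,
            father_sd_cm=7.9,
            p_missing_parents=0.16,
            birth_weight_mean_g=3356.0,
            birth_weight_sd_g=639.0,
            ga_min_weeks=34.0,
            p_missing_ga=16.0 / 55.0,
            seed=seed,
        )
    if name == "ks_pubertal":
        return CohortSpec(
            n=n if n is not None else 35,
            group="ks",
            param_means=_KS_PUBERTAL_MOMENTS["means"],
            param_sds=_KS_PUBERTAL_MOMENTS["sds"],
            mother_mean_cm=167.0,
            mother_sd_cm=6.0,
            father_mean_cm=179.3,
            father_sd_cm=7.4,
            p_missing_parents=6.0 / 35.0,
            birth_weight_mean_g=3365.0,
            birth_weight_sd_g=607.0,
            ga_min_weeks=34.0,
            p_missing_ga=16.0 / 55.0,
            seed=seed,
        )
    raise KeyError(f"unknown preset {name!r}; use reference, ks or ks_pubertal")


def preset_specs(
    n_reference: int | None = None, n_ks: int | None = None, seed: int = 0
) -> tuple[CohortSpec, CohortSpec]:
    """The two shipped cohort presets (reference group, clinical group),
    sharing schedule and rounding settings."""
    return (
        get_preset("reference", n_reference, seed),
        get_preset("ks", n_ks, seed),
    )
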