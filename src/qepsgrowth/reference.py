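"""Reference construction and SD-score computation.

A :class:`ReferenceModel` is built from a fitted reference cohort: per-
variable Gaussian moments for every curve parameter and derived growth
variable, smoothed height-for-age mean/SD curves, and adult-height moments
used for mid-parental height scoring.  Scores are plain z-scores
``(value - mean) / SD``; the parameter distributions this package works
with are close enough to normal that no skew correction is applied.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core import PARAM_NAMES, DerivedGrowthVariables, ShapeConstants
from .fitting import FitResult, GrowthRecord
from .core import total_height

__all__ = [
    "ReferenceModel",
    "build_reference",
    "sds",
    "mph_sds",
    "mid_parental_height_cm",
    "diff_mph_tmax_sds",
    "apply_reference",
]

MIN_REFERENCE_N = 30

#: Tanner target-height convention for boys (cm added to the mother's
#: height before averaging with the father's).
MPH_BOY_OFFSET_CM = 13.0

_SDS_VARIABLES = tuple(
    name
    for name in DerivedGrowthVariables.FIELDS
    if name not in ("t_max_sds", "diff_mph_tmax_sds")
) + PARAM_NAMES

_BIRTH_VARIABLES = ("birth_weight_g", "birth_length_cm")


@dataclass
class ReferenceModel:
    variables: dict[str, tuple[float, float]]  # name -> (mean, sd)
    height_age_grid: np.ndarray
    height_mean_curve: np.ndarray
    height_sd_curve: np.ndarray
    adult_male_mean_cm: float
    adult_male_sd_cm: float
    adult_female_mean_cm: float
    adult_female_sd_cm: float
    n: int
    shape: ShapeConstants

    def mean(self, variable: str) -> float:
        return self.variables[variable][0]

    def sd(self, variable: str) -> float:
        return self.variables[variable][1]

    def height_sds(self, age_years, height_cm):
        """Height-for-age z-score by interpolation on the reference grid."""
        m = np.interp(age_years, self.height_age_grid, self.height_mean_curve)
        s = np.interp(age_years, self.height_age_grid, self.height_sd_curve)
        return (np.asarray(height_cm, dtype=float) - m) / s

    def to_json(self, path) -> None:
        payload = {
            "variables": {k: list(v) for k, v in self.variables.items()},
            "height_age_grid": self.height_age_grid.tolist(),
            "height_mean_curve": self.height_mean_curve.tolist(),
            "height_sd_curve": self.height_sd_curve.tolist(),
            "adult_male_mean_cm": self.adult_male_mean_cm,
            "adult_male_sd_cm": self.adult_male_sd_cm,
            "adult_female_mean_cm": self.adult_female_mean_cm,
            "adult_female_sd_cm": self.adult_female_sd_cm,
            "n": self.n,
            "shape": {
                "t0_years": self.shape.t0_years,
                "age_qmax_years": self.shape.age_qmax_years,
                "e_tau_ref": self.shape.e_tau_ref,
                "p_quantile_offsets": [list(p) for p in self.shape.p_quantile_offsets],
                "stop_mode": self.shape.stop_mode,
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "ReferenceModel":
        with open(path) as fh:
            payload = json.load(fh)
        shape = payload["shape"]
        return cls(
            variables={k: tuple(v) for k, v in payload["variables"].items()},
            height_age_grid=np.asarray(payload["height_age_grid"]),
            height_mean_curve=np.asarray(payload["height_mean_curve"]),
            height_sd_curve=np.asarray(payload["height_sd_curve"]),
            adult_male_mean_cm=payload["adult_male_mean_cm"],
            adult_male_sd_cm=payload["adult_male_sd_cm"],
            adult_female_mean_cm=payload["adult_female_mean_cm"],
            adult_female_sd_cm=payload["adult_female_sd_cm"],
            n=payload["n"],
            shape=ShapeConstants(
                t0_years=shape["t0_years"],
                age_qmax_years=shape["age_qmax_years"],
                e_tau_ref=shape["e_tau_ref"],
                p_quantile_offsets=tuple(
                    (q, o) for q, o in shape["p_quantile_offsets"]
                ),
                stop_mode=shape["stop_mode"],
            ),
        )


def _moving_average(values: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return values
    return (
        pd.Series(values).rolling(window, center=True, min_periods=1).mean().to_numpy()
    )


def build_reference(
    fits: Sequence[FitResult],
    records: Sequence[GrowthRecord] | None = None,
    grid_step_years: float = 0.1,
    grid_max_years: float = 20.0,
    smooth_window_years: float = 0.5,
) -> ReferenceModel:
    """Sample moments of a fitted cohort, packaged for z-scoring.

    Height-for-age curves are pointwise moments of the forward-evaluated
    fitted curves on a 0.1-year grid, smoothed with a centred moving window.
    """
    if len(fits) < MIN_REFERENCE_N:
        raise ValueError(
            f"need at least {MIN_REFERENCE_N} fits to build a reference, got {len(fits)}"
        )

    table = {}
    for name in _SDS_VARIABLES:
        if name in PARAM_NAMES:
            idx = PARAM_NAMES.index(name)
            vals = np.array([f.params.as_array()[idx] for f in fits])
        else:
            vals = np.array([getattr(f.derived, name) for f in fits])
        table[name] = vals

    if records is not None:
        for name in _BIRTH_VARIABLES:
            vals = np.array(
                [getattr(r, name) for r in records if getattr(r, name) is not None],
                dtype=float,
            )
            if vals.size >= 2:
                table[name] = vals

    variables: dict[str, tuple[float, float]] = {}
    for name, vals in table.items():
        mean = float(np.mean(vals))
        sd = float(np.std(vals, ddof=1))
        if not sd > 1e-9:
            raise ValueError(f"degenerate reference: variable {name!r} has zero SD")
        variables[name] = (mean, sd)

    grid = np.round(np.arange(0.0, grid_max_years + 1e-9, grid_step_years), 10)
    curves = np.vstack([total_height(grid, f.params) for f in fits])
    window = max(1, int(round(smooth_window_years / grid_step_years)))
    mean_curve = _moving_average(curves.mean(axis=0), window)
    sd_curve = _moving_average(curves.std(axis=0, ddof=1), window)

    adult_mean, adult_sd = variables["t_max_cm"]
    return ReferenceModel(
        variables=variables,
        height_age_grid=grid,
        height_mean_curve=mean_curve,
        height_sd_curve=sd_curve,
        adult_male_mean_cm=adult_mean,
        adult_male_sd_cm=adult_sd,
        # No female cohort is fitted; carried as the male moments shifted by
        # the target-height offset so the MPH formula is self-consistent.
        adult_female_mean_cm=adult_mean - MPH_BOY_OFFSET_CM,
        adult_female_sd_cm=adult_sd,
        n=len(fits),
        shape=fits[0].params.shape,
    )


def sds(value: float, variable: str, ref: ReferenceModel) -> float:
    """Plain z-score of ``value`` against the reference moments."""
    if variable not in ref.variables:
        raise KeyError(f"unknown reference variable: {variable!r}")
    mean, sd_ = ref.variables[variable]
    return (value - mean) / sd_


def mid_parental_height_cm(
    mother_height_cm: float, father_height_cm: float
) -> float:
    """Tanner target height for a boy."""
    return (father_height_cm + mother_height_cm + MPH_BOY_OFFSET_CM) / 2.0


def mph_sds(
    mother_height_cm: float | None,
    father_height_cm: float | None,
    ref: ReferenceModel,
) -> float | None:
    """Mid-parental height scored against adult male moments.

    Returns ``None`` when either parent is missing so the individual drops
    out of family-difference summaries.
    """
    if mother_height_cm is None or father_height_cm is None:
        return None
    mph = mid_parental_height_cm(mother_height_cm, father_height_cm)
    return (mph - ref.adult_male_mean_cm) / ref.adult_male_sd_cm


def diff_mph_tmax_sds(
    t_max_sds: float | None, mph_sds_value: float | None
) -> float | None:
    """Intrafamilial height difference: adult-height SDS minus MPH SDS."""
    if t_max_sds is None or mph_sds_value is None:
        return None
    return t_max_sds - mph_sds_value


def apply_reference(
    fits: Sequence[FitResult],
    records: Sequence[GrowthRecord],
    ref: ReferenceModel,
) -> pd.DataFrame:
    """Fill SDS fields on each fit's derived variables and return the
    per-individual variable table (one row per fit, SDS columns included)."""
    by_id = {r.id: r for r in records}
    rows = []
    for f in fits:
        rec = by_id.get(f.record_id)
        t_sds = sds(f.derived.t_max_cm, "t_max_cm", ref)
        m_sds = (
            mph_sds(rec.mother_height_cm, rec.father_height_cm, ref)
            if rec is not None
            else None
        )
        f.derived.t_max_sds = t_sds
        f.derived.diff_mph_tmax_sds = diff_mph_tmax_sds(t_sds, m_sds)
        row = {"id": f.record_id, "group": f.group}
        row.update(f.derived.as_dict())
        row["mph_sds"] = m_sds
        rows.append(row)
    return pd.DataFrame(rows)
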