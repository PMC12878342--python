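"""Individual-level model fitting: data quality screening, the operational
adult-height rule, and weighted nonlinear least squares for the six curve
parameters with asymptotic confidence intervals."""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .core import (
    ComputationError,
    DerivedGrowthVariables,
    PARAM_NAMES,
    QEPSParams,
    ShapeConstants,
    derive_variables,
    total_height,
)

log = logging.getLogger(__name__)

__all__ = [
    "Measurement",
    "GrowthRecord",
    "QCThresholds",
    "QCReport",
    "FitConfig",
    "FitResult",
    "IneligibleRecordError",
    "default_measurement_sd",
    "qc_screen",
    "adult_height_from_data",
    "fit_individual",
    "fit_cohort",
    "read_records",
    "write_records",
    "fits_to_frame",
    "write_fit_results",
]

#: Assumed measurement SDs (cm): supine infant length on a measuring mat is
#: recorded to the nearest 0.5 cm, standing height to the nearest 0.1 cm but
#: with posture/technique noise dominating.
SD_INFANCY_CM = 0.6
SD_LATER_CM = 0.3
INFANCY_CUTOFF_YEARS = 2.0

#: Annualised growth below this rate marks attained adult height (cm/year).
ADULT_VELOCITY_CUTOFF = 0.5
_ADULT_WINDOW_YEARS = 0.8
_ADULT_MIN_AGE = 15.0


def default_measurement_sd(age_years: float) -> float:
    return SD_INFANCY_CM if age_years < INFANCY_CUTOFF_YEARS else SD_LATER_CM


class Measurement(NamedTuple):
    age_years: float
    height_cm: float
    source: str = "clinic"
    assumed_sd_cm: float | None = None

    @property
    def sd_cm(self) -> float:
        if self.assumed_sd_cm is not None:
            return self.assumed_sd_cm
        return default_measurement_sd(self.age_years)


@dataclass
class GrowthRecord:
    """One individual's longitudinal measurement series plus covariates."""

    id: str
    measurements: list[Measurement]
    group: str = "unknown"
    sex: str = "male"
    ga_weeks: float | None = None
    birth_weight_g: float | None = None
    birth_length_cm: float | None = None
    mother_height_cm: float | None = None
    father_height_cm: float | None = None

    def __post_init__(self) -> None:
        if not self.measurements:
            raise ValueError(f"record {self.id}: no measurements")
        ages = [m.age_years for m in self.measurements]
        if any(a < 0 for a in ages):
            raise ValueError(f"record {self.id}: negative measurement age")
        if any(b <= a for a, b in zip(ages, ages[1:])):
            raise ValueError(f"record {self.id}: ages must strictly increase")
        for m in self.measurements:
            if not 20.0 < m.height_cm < 230.0:
                raise ValueError(
                    f"record {self.id}: height {m.height_cm} cm out of range"
                )

    @property
    def ages(self) -> np.ndarray:
        return np.array([m.age_years for m in self.measurements])

    @property
    def heights(self) -> np.ndarray:
        return np.array([m.height_cm for m in self.measurements])

    @property
    def sds(self) -> np.ndarray:
        return np.array([m.sd_cm for m in self.measurements])

    def shape_constants(self, stop_mode: str = "hard_cap") -> ShapeConstants:
        # GA correction enters only through the fetal origin t0; missing GA
        # is imputed as term (40 weeks).
        if self.sex == "female":
            return ShapeConstants.female(self.ga_weeks, stop_mode=stop_mode)
        return ShapeConstants.male(self.ga_weeks, stop_mode=stop_mode)


@dataclass(frozen=True)
class QCThresholds:
    """Eligibility rules for fitting.

    The originating clinical workflow excluded series with "excessively
    long" measurement gaps without publishing thresholds; these defaults are
    declared, not inferred.
    """

    min_infancy_points: int = 3  # below 2 y
    min_childhood_points: int = 3  # 2-10 y
    max_childhood_gap_years: float = 4.0
    min_puberty_points: int = 3  # 10-18 y
    max_puberty_gap_years: float = 2.0
    require_adult_height: bool = True


@dataclass
class QCReport:
    max_gap_childhood_years: float
    max_gap_puberty_years: float
    n_infancy: int
    n_childhood: int
    n_puberty: int
    n_adult: int
    eligible_prepubertal: bool
    eligible_pubertal: bool
    exclusion_reasons: list[str] = field(default_factory=list)


class AdultHeightResult(NamedTuple):
    height_cm: float | None
    attained: bool
    reason: str = ""


class IneligibleRecordError(ValueError):
    def __init__(self, record_id: str, qc: QCReport):
        self.qc = qc
        super().__init__(
            f"record {record_id} ineligible: {'; '.join(qc.exclusion_reasons)}"
        )


def _max_gap(ages: np.ndarray, lo: float, hi: float) -> float:
    """Largest interval between consecutive measurements overlapping the
    open age window (lo, hi)."""
    gaps = [
        b - a
        for a, b in zip(ages, ages[1:])
        if b > lo and a < hi
    ]
    return max(gaps, default=0.0)


def adult_height_from_data(record: GrowthRecord) -> AdultHeightResult:
    """Last measured height and whether adult height is attained.

    Adult height is operationally the height measured once the annualised
    growth rate over the final window of at least 0.8 years has dropped
    below 0.5 cm/year.
    """
    ages, heights = record.ages, record.heights
    late = ages > _ADULT_MIN_AGE
    if late.sum() < 2:
        return AdultHeightResult(
            float(heights[-1]) if len(heights) else None,
            False,
            f"fewer than 2 measurements after {_ADULT_MIN_AGE:g} y",
        )
    a_last, h_last = float(ages[-1]), float(heights[-1])
    window = np.flatnonzero(ages <= a_last - _ADULT_WINDOW_YEARS)
    if window.size == 0:
        return AdultHeightResult(
            h_last, False, "no 0.8-year window before the final measurement"
        )
    i = window[-1]
    rate = (h_last - float(heights[i])) / (a_last - float(ages[i]))
    if rate < ADULT_VELOCITY_CUTOFF:
        return AdultHeightResult(h_last, True)
    return AdultHeightResult(
        h_last, False, f"still growing {rate:.2f} cm/y over final window"
    )


def qc_screen(
    record: GrowthRecord, thresholds: QCThresholds | None = None
) -> QCReport:
    """Deterministic eligibility screening of one measurement series."""
    thr = thresholds if thresholds is not None else QCThresholds()
    ages = record.ages
    n_inf = int(np.sum(ages < INFANCY_CUTOFF_YEARS))
    n_child = int(np.sum((ages >= INFANCY_CUTOFF_YEARS) & (ages < 10.0)))
    n_pub = int(np.sum((ages >= 10.0) & (ages < 18.0)))
    n_adult = int(np.sum(ages >= 18.0))
    gap_child = _max_gap(ages, 0.0, 10.0)
    gap_pub = _max_gap(ages, 10.0, 18.0)

    reasons: list[str] = []
    if n_inf < thr.min_infancy_points:
        reasons.append(
            f"only {n_inf} measurements below 2 y (need {thr.min_infancy_points})"
        )
    if n_child < thr.min_childhood_points:
        reasons.append(
            f"only {n_child} measurements in 2-10 y (need {thr.min_childhood_points})"
        )
    if gap_child > thr.max_childhood_gap_years:
        reasons.append(
            f"childhood gap {gap_child:.1f} y > {thr.max_childhood_gap_years:g} y"
        )
    eligible_pre = not reasons

    pub_reasons: list[str] = []
    if n_pub < thr.min_puberty_points:
        pub_reasons.append(
            f"only {n_pub} measurements in 10-18 y (need {thr.min_puberty_points})"
        )
    if gap_pub > thr.max_puberty_gap_years:
        pub_reasons.append(
            f"puberty gap {gap_pub:.1f} y > {thr.max_puberty_gap_years:g} y"
        )
    if thr.require_adult_height:
        adult = adult_height_from_data(record)
        if not adult.attained:
            pub_reasons.append(f"adult height not attained: {adult.reason}")
    eligible_pub = eligible_pre and not pub_reasons

    return QCReport(
        max_gap_childhood_years=gap_child,
        max_gap_puberty_years=gap_pub,
        n_infancy=n_inf,
        n_childhood=n_child,
        n_puberty=n_pub,
        n_adult=n_adult,
        eligible_prepubertal=eligible_pre,
        eligible_pubertal=eligible_pub,
        exclusion_reasons=reasons + pub_reasons,
    )


# Multi-start centre: healthy-reference group means of the six parameters.
START_MEANS = np.array([65.1, 104.1, 17.4, 1.01, 1.01, 13.8])
_EPS = 1e-6
LOWER_BOUNDS = np.array([5.0, 30.0, 0.5, 0.4 + _EPS, 0.4 + _EPS, 8.0 + _EPS])
UPPER_BOUNDS = np.array([120.0, 180.0, 60.0, 2.5 - _EPS, 2.5 - _EPS, 20.0 - _EPS])


@dataclass(frozen=True)
class FitConfig:
    n_starts: int = 7
    seed: int = 0
    perturbation: float = 0.2
    eligibility: str = "pubertal"  # pubertal | prepubertal | none
    stop_mode: str = "hard_cap"
    ftol: float = 1e-10
    xtol: float = 1e-10
    qc_thresholds: QCThresholds = field(default_factory=QCThresholds)


@dataclass
class FitResult:
    record_id: str
    group: str
    params: QEPSParams
    derived: DerivedGrowthVariables
    residual_sd_cm: float
    ci_half_widths: dict[str, float]
    converged: bool
    qc: QCReport
    n_measurements: int
    cost: float
    objective_trace: list[float] = field(default_factory=list)

    @property
    def p_identifiable(self) -> bool:
        return math.isfinite(self.ci_half_widths["p_heightscale_cm"])


def _starts(config: FitConfig) -> np.ndarray:
    rng = np.random.default_rng(config.seed)
    starts = [START_MEANS]
    for _ in range(config.n_starts - 1):
        factor = 1.0 + rng.uniform(-config.perturbation, config.perturbation, 6)
        starts.append(START_MEANS * factor)
    return np.clip(np.array(starts), LOWER_BOUNDS, UPPER_BOUNDS)


def fit_individual(record: GrowthRecord, config: FitConfig | None = None) -> FitResult:
    """Weighted nonlinear least squares for one individual.

    Minimises sum of ``((h_i - T(age_i)) / sd_i)**2`` over the six
    parameters from multiple seeded starts; the best converged solution
    wins, with ties broken by proximity to the start-centre means.
    """
    config = config if config is not None else FitConfig()
    qc = qc_screen(record, config.qc_thresholds)
    if config.eligibility == "pubertal" and not qc.eligible_pubertal:
        raise IneligibleRecordError(record.id, qc)
    if config.eligibility == "prepubertal" and not qc.eligible_prepubertal:
        raise IneligibleRecordError(record.id, qc)

    shape = record.shape_constants(config.stop_mode)
    ages, heights, sds = record.ages, record.heights, record.sds
    trace: list[float] = []

    def residuals(theta):
        p = QEPSParams.from_array(theta, shape)
        r = (heights - total_height(ages, p)) / sds
        cost = 0.5 * float(np.dot(r, r))
        if not trace or cost < trace[-1]:
            trace.append(cost)
        return r

    best = None
    best_key = None
    any_success = False
    for theta0 in _starts(config):
        try:
            res = least_squares(
                residuals,
                theta0,
                bounds=(LOWER_BOUNDS, UPPER_BOUNDS),
                ftol=config.ftol,
                xtol=config.xtol,
                method="trf",
            )
        except Exception as exc:  # pragma: no cover - optimizer pathologies
            log.warning("start failed for %s: %s", record.id, exc)
            continue
        any_success = any_success or bool(res.success)
        key = (round(res.cost, 12), float(np.linalg.norm(res.x - START_MEANS)))
        if best is None or key < best_key:
            best, best_key = res, key
    if best is None:
        raise ComputationError(f"all optimizer starts failed for record {record.id}")

    params = QEPSParams.from_array(best.x, shape)
    n, k = len(ages), 6
    raw = heights - total_height(ages, params)
    residual_sd = float(np.sqrt(np.sum(raw**2) / (n - k))) if n > k else float("nan")

    ci = dict.fromkeys(PARAM_NAMES, float("inf"))
    if n > k:
        jtj = best.jac.T @ best.jac
        s2 = 2.0 * best.cost / (n - k)
        try:
            cov = s2 * np.linalg.inv(jtj)
            half = 1.96 * np.sqrt(np.clip(np.diag(cov), 0.0, None))
            ci = dict(zip(PARAM_NAMES, (float(h) for h in half)))
        except np.linalg.LinAlgError:
            pass

    # Identifiability guard: without data past mid-puberty the pubertal
    # amplitude is unconstrained.
    if not np.any(ages > params.age_p50_years + 1.0):
        for name in ("p_heightscale_cm", "p_timescale", "age_p50_years"):
            ci[name] = float("inf")
        if qc.eligible_pubertal:
            qc.eligible_pubertal = False
            qc.exclusion_reasons.append("no measurement after mid-puberty + 1 y")

    return FitResult(
        record_id=record.id,
        group=record.group,
        params=params,
        derived=derive_variables(params),
        residual_sd_cm=residual_sd,
        ci_half_widths=ci,
        converged=any_success,
        qc=qc,
        n_measurements=n,
        cost=float(best.cost),
        objective_trace=trace,
    )


def fit_cohort(
    records: Sequence[GrowthRecord],
    config: FitConfig | None = None,
    skip_ineligible: bool = True,
) -> list[FitResult]:
    """Fit every eligible record; ineligible ones are logged and skipped."""
    config = config if config is not None else FitConfig()
    fits = []
    for rec in records:
        try:
            fits.append(fit_individual(rec, config))
        except IneligibleRecordError as exc:
            if not skip_ineligible:
                raise
            log.info("skipping %s", exc)
    return fits


# ---------------------------------------------------------------------------
# I/O: long-format measurement CSV plus a per-individual covariate CSV.

MEASUREMENT_COLUMNS = ["id", "age_years", "height_cm", "source"]
COVARIATE_COLUMNS = [
    "id",
    "group",
    "sex",
    "ga_weeks",
    "birth_weight_g",
    "birth_length_cm",
    "mother_height_cm",
    "father_height_cm",
]


def read_records(
    measurements_csv, covariates_csv=None
) -> list[GrowthRecord]:
    """Load growth records from long-format CSV.

    ``measurements_csv`` needs columns id, age_years, height_cm and
    optionally source; ``covariates_csv`` (optional) carries one row per
    individual with the covariate columns.
    """
    df = pd.read_csv(measurements_csv)
    missing = {"id", "age_years", "height_cm"} - set(df.columns)
    if missing:
        raise ValueError(f"measurement CSV missing columns: {sorted(missing)}")
    if "source" not in df.columns:
        df["source"] = "clinic"
    cov: dict[str, dict] = {}
    if covariates_csv is not None:
        cdf = pd.read_csv(covariates_csv)
        for row in cdf.to_dict("records"):
            cov[str(row["id"])] = row

    records = []
    for rid, grp in df.groupby("id", sort=False):
        grp = grp.sort_values("age_years")
        meas = [
            Measurement(float(r.age_years), float(r.height_cm), str(r.source))
            for r in grp.itertuples()
        ]
        c = cov.get(str(rid), {})

        def _num(key):
            v = c.get(key)
            return None if v is None or (isinstance(v, float) and math.isnan(v)) else float(v)

        records.append(
            GrowthRecord(
                id=str(rid),
                measurements=meas,
                group=str(c.get("group", "unknown")),
                sex=str(c.get("sex", "male")),
                ga_weeks=_num("ga_weeks"),
                birth_weight_g=_num("birth_weight_g"),
                birth_length_cm=_num("birth_length_cm"),
                mother_height_cm=_num("mother_height_cm"),
                father_height_cm=_num("father_height_cm"),
            )
        )
    return records


def write_records(
    records: Sequence[GrowthRecord], measurements_csv, covariates_csv=None
) -> None:
    rows = [
        {
            "id": rec.id,
            "age_years": m.age_years,
            "height_cm": m.height_cm,
            "source": m.source,
        }
        for rec in records
        for m in rec.measurements
    ]
    pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS).to_csv(
        measurements_csv, index=False
    )
    if covariates_csv is not None:
        crows = [
            {
                "id": rec.id,
                "group": rec.group,
                "sex": rec.sex,
                "ga_weeks": rec.ga_weeks,
                "birth_weight_g": rec.birth_weight_g,
                "birth_length_cm": rec.birth_length_cm,
                "mother_height_cm": rec.mother_height_cm,
                "father_height_cm": rec.father_height_cm,
            }
            for rec in records
        ]
        pd.DataFrame(crows, columns=COVARIATE_COLUMNS).to_csv(
            covariates_csv, index=False
        )


def fits_to_frame(fits: Sequence[FitResult]) -> pd.DataFrame:
    """One row per fitted individual: parameters, derived variables and
    diagnostics."""
    rows = []
    for f in fits:
        row = {"id": f.record_id, "group": f.group}
        row.update(zip(PARAM_NAMES, f.params.as_array()))
        row.update(f.derived.as_dict())
        row.update({f"ci_{k}": v for k, v in f.ci_half_widths.items()})
        row.update(
            {
                "residual_sd_cm": f.residual_sd_cm,
                "converged": f.converged,
                "n_measurements": f.n_measurements,
                "cost": f.cost,
            }
        )
        rows.append(row)
    return pd.DataFrame(rows)


def write_fit_results(
    fits: Sequence[FitResult], csv_path, json_path=None
) -> None:
    fits_to_frame(fits).to_csv(csv_path, index=False)
    if json_path is not None:
        diag = {
            f.record_id: {
                "converged": f.converged,
                "cost": f.cost,
                "n_measurements": f.n_measurements,
                "residual_sd_cm": f.residual_sd_cm,
                "ci_half_widths": f.ci_half_widths,
                "eligible_prepubertal": f.qc.eligible_prepubertal,
                "eligible_pubertal": f.qc.eligible_pubertal,
                "exclusion_reasons": f.qc.exclusion_reasons,
                "objective_trace": f.objective_trace,
            }
            for f in fits
        }
        with open(json_path, "w") as fh:
            json.dump(diag, fh, indent=1, allow_nan=True)
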