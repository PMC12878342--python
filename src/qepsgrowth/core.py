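"""Deterministic forward model of height growth and derived-variable extraction.

Total height is decomposed additively into four components::

    T(age) = E(age) + QS(age) + P(age),      QS(age) = Q(age) - S(age)

* ``Q`` — quadratic *basic* growth, rising from zero at the fetal origin
  ``t0`` to its vertex (maximum) at ``age_qmax_years``; its velocity
  declines linearly to zero there.
* ``E`` — saturating exponential capturing fetal/infancy growth.
* ``P`` — monotone sigmoid capturing the puberty-specific spurt, with a
  mildly right-skewed fixed shape calibrated through quantile offsets.
* ``S`` — stop function terminating basic growth at the end of puberty.

Six free parameters describe an individual (three amplitudes, two time
scales, one location); everything else is carried by :class:`ShapeConstants`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Mapping

import numpy as np
from scipy.interpolate import CubicHermiteSpline, PchipInterpolator
from scipy.optimize import brentq, minimize_scalar
from scipy.special import expit, logit

__all__ = [
    "DomainError",
    "ComputationError",
    "ShapeConstants",
    "QEPSParams",
    "DerivedGrowthVariables",
    "t0_from_gestational_age",
    "calibrate_e_tau",
    "calibrate_p_offsets",
    "q_function",
    "e_function",
    "p_function",
    "s_function",
    "qs_function",
    "total_height",
    "total_velocity",
    "pubertal_p_gain",
    "stopped_basic_max",
    "adult_height_from_components",
    "derive_variables",
]

WEEKS_PER_YEAR = 365.2425 / 7.0

#: Gestational age assumed when none is recorded (term birth).
DEFAULT_GA_WEEKS = 40.0

#: Age (years) at which the quadratic basic component completes.
AGE_QMAX_MALE = 21.5
AGE_QMAX_FEMALE = 19.1

# Calibration anchors for the shipped male shape: group-mean milestone ages
# of a healthy reference cohort at the corresponding group-mean time scales.
REF_AGE_E99 = 1.88
REF_E_TIMESCALE = 1.01
REF_AGE_P50 = 13.8
REF_P_TIMESCALE = 1.01
REF_P_QUANTILE_AGES = {0.01: 10.8, 0.05: 11.8, 0.95: 16.1, 0.99: 17.6}

# Padding (in unit-timescale offset units) between the outermost calibrated
# quantiles and the exact start/end of the pubertal sigmoid's support.  The
# tight upper pad guarantees a hard growth plateau shortly after the 99%
# milestone for any admissible p_timescale.
_P_SUPPORT_PAD_LO = 0.60
_P_SUPPORT_PAD_HI = 0.35

_LN100 = math.log(100.0)


class DomainError(ValueError):
    """An age outside the model's domain (before the fetal origin)."""


class ComputationError(RuntimeError):
    """A numeric search (root finding / optimisation) failed to converge."""


def t0_from_gestational_age(ga_weeks: float | None) -> float:
    """Postnatal-axis fetal origin: 6 weeks after conception, in years.

    Conception is 2 weeks of gestational age, so the origin sits at
    ``ga_weeks - 8`` weeks before birth.  Missing GA is imputed as term
    (40 weeks).
    """
    if ga_weeks is None:
        ga_weeks = DEFAULT_GA_WEEKS
    if not 20.0 <= ga_weeks <= 46.0:
        raise ValueError(f"implausible gestational age: {ga_weeks} weeks")
    return -(ga_weeks - 8.0) / WEEKS_PER_YEAR


def calibrate_e_tau(
    age_e99_years: float, e_timescale: float, t0_years: float
) -> float:
    """Reference time constant of E such that 99% of the amplitude is
    reached at ``age_e99_years`` when the individual time scale equals
    ``e_timescale``."""
    return (age_e99_years - t0_years) / (_LN100 * e_timescale)


def calibrate_p_offsets(
    age_p50_years: float,
    quantile_ages: Mapping[float, float],
    p_timescale: float,
) -> dict[float, float]:
    """Unit-timescale quantile offsets of the pubertal sigmoid.

    Each offset is the (signed) distance from the mid-puberty age to the age
    at which the given fraction of the pubertal amplitude is attained,
    divided by the time scale at which those ages were observed.
    """
    offsets = {0.5: 0.0}
    for q, age in quantile_ages.items():
        offsets[q] = (age - age_p50_years) / p_timescale
    return dict(sorted(offsets.items()))


_DEFAULT_T0 = t0_from_gestational_age(None)
_DEFAULT_E_TAU = calibrate_e_tau(REF_AGE_E99, REF_E_TIMESCALE, _DEFAULT_T0)
_DEFAULT_P_OFFSETS = tuple(
    calibrate_p_offsets(REF_AGE_P50, REF_P_QUANTILE_AGES, REF_P_TIMESCALE).items()
)


@dataclass(frozen=True)
class ShapeConstants:
    """Fixed shape of the model, shared across individuals of one sex.

    Attributes
    ----------
    t0_years:
        Fetal origin on the postnatal age axis (negative, years).
    age_qmax_years:
        Age at which basic (Q) growth would complete.
    e_tau_ref:
        Reference exponential time constant (years) of the E component.
    p_quantile_offsets:
        ``((fraction, offset_years), ...)`` — signed distance from the
        mid-puberty age to each fractional milestone of the P component, at
        unit time scale.  The 50% offset is zero.
    stop_mode:
        ``"hard_cap"`` freezes basic growth at the 95% pubertal milestone;
        ``"smooth"`` ramps it down continuously from mid-puberty with the
        same stopped total; ``"none"`` disables the stop (S identically
        zero), useful for decomposition checks.
    """

    t0_years: float = _DEFAULT_T0
    age_qmax_years: float = AGE_QMAX_MALE
    e_tau_ref: float = _DEFAULT_E_TAU
    p_quantile_offsets: tuple[tuple[float, float], ...] = _DEFAULT_P_OFFSETS
    stop_mode: str = "hard_cap"

    def __post_init__(self) -> None:
        if not self.t0_years < 0:
            raise ValueError("t0_years must be negative")
        if not self.age_qmax_years > 18:
            raise ValueError("age_qmax_years must exceed 18")
        if not self.e_tau_ref > 0:
            raise ValueError("e_tau_ref must be positive")
        if self.stop_mode not in ("hard_cap", "smooth", "none"):
            raise ValueError(f"unknown stop_mode: {self.stop_mode!r}")
        offs = dict(self.p_quantile_offsets)
        if 0.5 not in offs or offs[0.5] != 0.0:
            raise ValueError("p_quantile_offsets must map 0.5 -> 0.0")
        qs = sorted(offs)
        vals = [offs[q] for q in qs]
        if any(b <= a for a, b in zip(vals, vals[1:])):
            raise ValueError("quantile offsets must increase with the fraction")

    @classmethod
    def male(cls, ga_weeks: float | None = None, stop_mode: str = "hard_cap"):
        return cls(
            t0_years=t0_from_gestational_age(ga_weeks), stop_mode=stop_mode
        )

    @classmethod
    def female(cls, ga_weeks: float | None = None, stop_mode: str = "hard_cap"):
        # Carried for completeness; untested against data.
        return cls(
            t0_years=t0_from_gestational_age(ga_weeks),
            age_qmax_years=AGE_QMAX_FEMALE,
            stop_mode=stop_mode,
        )

    def offset_for(self, fraction: float) -> float:
        offs = dict(self.p_quantile_offsets)
        try:
            return offs[fraction]
        except KeyError:
            raise KeyError(f"no calibrated offset for fraction {fraction}")

    def with_ga(self, ga_weeks: float | None) -> "ShapeConstants":
        return replace(self, t0_years=t0_from_gestational_age(ga_weeks))


class _PShape:
    """Monotone C1 sigmoid through the calibrated quantile knots.

    The core runs through a shape-preserving cubic (PCHIP) fitted in logit
    space — logit-space interpolation keeps the velocity peak near the
    median, as a growth spurt requires, while honouring the skewed quantile
    offsets exactly.  Beyond the outermost knots, cubic Hermite tails close
    the sigmoid to exactly 0/1 at padded support edges so late-adolescent
    velocity vanishes identically.
    """

    def __init__(self, offsets: tuple[tuple[float, float], ...]):
        offs = dict(offsets)
        qs = sorted(offs)
        u = np.array([offs[q] for q in qs])
        z = logit(np.asarray(qs))
        self._h = PchipInterpolator(u, z)
        self._hd = self._h.derivative()
        self.u_first, self.u_last = u[0], u[-1]
        self.q_first, self.q_last = qs[0], qs[-1]
        self.lo = u[0] - _P_SUPPORT_PAD_LO
        self.hi = u[-1] + _P_SUPPORT_PAD_HI
        m_first = self.q_first * (1 - self.q_first) * float(self._hd(u[0]))
        m_last = self.q_last * (1 - self.q_last) * float(self._hd(u[-1]))
        self._left = CubicHermiteSpline(
            [self.lo, u[0]], [0.0, self.q_first], [0.0, m_first]
        )
        self._right = CubicHermiteSpline(
            [u[-1], self.hi], [self.q_last, 1.0], [m_last, 0.0]
        )
        self._left_d = self._left.derivative()
        self._right_d = self._right.derivative()
        grid = np.linspace(self.lo, self.hi, 4001)
        if np.any(np.diff(self.cdf(grid)) < -1e-12):
            raise ValueError("quantile offsets yield a non-monotone sigmoid")

    def cdf(self, u):
        u = np.asarray(u, dtype=float)
        out = np.empty_like(u)
        out[u <= self.lo] = 0.0
        out[u >= self.hi] = 1.0
        m = (u > self.lo) & (u < self.u_first)
        out[m] = self._left(u[m])
        m = (u >= self.u_first) & (u <= self.u_last)
        out[m] = expit(self._h(u[m]))
        m = (u > self.u_last) & (u < self.hi)
        out[m] = self._right(u[m])
        return out

    def pdf(self, u):
        u = np.asarray(u, dtype=float)
        out = np.zeros_like(u)
        m = (u > self.lo) & (u < self.u_first)
        out[m] = self._left_d(u[m])
        m = (u >= self.u_first) & (u <= self.u_last)
        f = expit(self._h(u[m]))
        out[m] = f * (1.0 - f) * self._hd(u[m])
        m = (u > self.u_last) & (u < self.hi)
        out[m] = self._right_d(u[m])
        return out


@lru_cache(maxsize=32)
def _p_shape(offsets: tuple[tuple[float, float], ...]) -> _PShape:
    return _PShape(offsets)


def _p_cdf(u, shape: ShapeConstants):
    return _p_shape(shape.p_quantile_offsets).cdf(u)


def _p_pdf(u, shape: ShapeConstants):
    return _p_shape(shape.p_quantile_offsets).pdf(u)


@dataclass(frozen=True)
class QEPSParams:
    """The six fitted parameters of one individual's growth curve.

    Amplitudes equal component asymptotes (``e_heightscale_cm`` is the adult
    contribution of E, and so on); time scales are unitless multipliers of
    the reference shape near 1; ``age_p50_years`` locates mid-puberty.
    """

    e_heightscale_cm: float
    q_heightscale_cm: float
    p_heightscale_cm: float
    e_timescale: float
    p_timescale: float
    age_p50_years: float
    shape: ShapeConstants = field(default_factory=ShapeConstants)

    def __post_init__(self) -> None:
        for name in ("e_heightscale_cm", "q_heightscale_cm", "p_heightscale_cm"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        for name in ("e_timescale", "p_timescale"):
            if not 0.4 < getattr(self, name) < 2.5:
                raise ValueError(f"{name} must lie in (0.4, 2.5)")
        if not 8.0 < self.age_p50_years < 20.0:
            raise ValueError("age_p50_years must lie in (8, 20)")

    # Asymptote aliases
    @property
    def e_max(self) -> float:
        return self.e_heightscale_cm

    @property
    def q_max(self) -> float:
        return self.q_heightscale_cm

    @property
    def p_max(self) -> float:
        return self.p_heightscale_cm

    @property
    def age_p95_years(self) -> float:
        return self.age_p50_years + self.shape.offset_for(0.95) * self.p_timescale

    def as_array(self) -> np.ndarray:
        return np.array(
            [
                self.e_heightscale_cm,
                self.q_heightscale_cm,
                self.p_heightscale_cm,
                self.e_timescale,
                self.p_timescale,
                self.age_p50_years,
            ]
        )

    @classmethod
    def from_array(cls, theta, shape: ShapeConstants | None = None):
        shape = shape if shape is not None else ShapeConstants()
        e, q, p, ets, pts, p50 = (float(x) for x in theta)
        return cls(e, q, p, ets, pts, p50, shape=shape)


PARAM_NAMES = (
    "e_heightscale_cm",
    "q_heightscale_cm",
    "p_heightscale_cm",
    "e_timescale",
    "p_timescale",
    "age_p50_years",
)


def _check_domain(age, t0: float):
    age = np.asarray(age, dtype=float)
    if np.any(age < t0 - 1e-12):
        raise DomainError(f"age below fetal origin t0 = {t0:.4f} y")
    return age


def _scalar_like(value, age_in):
    if np.isscalar(age_in) or (
        isinstance(age_in, np.ndarray) and age_in.ndim == 0
    ):
        return float(value)
    return value


def q_function(age, params: QEPSParams):
    """Basic quadratic growth (cm): zero at t0, vertex Q_max at age_qmax."""
    shape = params.shape
    a = _check_domain(age, shape.t0_years)
    A, t0 = shape.age_qmax_years, shape.t0_years
    capped = np.minimum(a, A)
    val = params.q_max * (1.0 - ((A - capped) / (A - t0)) ** 2)
    return _scalar_like(val, age)


def q_velocity(age, params: QEPSParams):
    shape = params.shape
    a = _check_domain(age, shape.t0_years)
    A, t0 = shape.age_qmax_years, shape.t0_years
    vel = np.where(a < A, 2.0 * params.q_max * (A - np.minimum(a, A)) / (A - t0) ** 2, 0.0)
    return _scalar_like(vel, age)


def e_function(age, params: QEPSParams):
    """Saturating exponential infancy growth (cm): zero at t0, asymptote E_max."""
    shape = params.shape
    a = _check_domain(age, shape.t0_years)
    tau = shape.e_tau_ref * params.e_timescale
    val = params.e_max * (1.0 - np.exp(-(a - shape.t0_years) / tau))
    return _scalar_like(val, age)


def e_velocity(age, params: QEPSParams):
    shape = params.shape
    a = _check_domain(age, shape.t0_years)
    tau = shape.e_tau_ref * params.e_timescale
    vel = params.e_max / tau * np.exp(-(a - shape.t0_years) / tau)
    return _scalar_like(vel, age)


def p_function(age, params: QEPSParams):
    """Puberty-specific sigmoid growth (cm), 0 -> P_max, median at age_p50."""
    a = np.asarray(age, dtype=float)
    u = (a - params.age_p50_years) / params.p_timescale
    return _scalar_like(params.p_max * _p_cdf(u, params.shape), age)


def p_velocity(age, params: QEPSParams):
    a = np.asarray(age, dtype=float)
    u = (a - params.age_p50_years) / params.p_timescale
    return _scalar_like(
        params.p_max * _p_pdf(u, params.shape) / params.p_timescale, age
    )


_SMOOTH_RAMP_YEARS = 1.0


def _smooth_stop_pieces(params: QEPSParams):
    """Constants of the smooth stop: S velocity is ``alpha * s(x) * Q'``
    with a cubic smoothstep ``s`` over a short ramp from mid-puberty, scaled
    so the accumulated stop equals the hard-cap stopped total exactly when
    basic growth completes.  This keeps both S and QS monotone and the
    velocity continuous at the stop onset."""
    shape = params.shape
    A, t0 = shape.age_qmax_years, shape.t0_years
    s0 = params.age_p50_years
    delta = min(_SMOOTH_RAMP_YEARS, (A - s0) / 2.0)
    c = 2.0 * params.q_max / (A - t0) ** 2
    s_total = params.q_max - stopped_basic_max(params.q_max, params.age_p95_years, shape)

    def unscaled(t):
        t = np.minimum(np.asarray(t, dtype=float), A)
        x = np.clip((t - s0) / delta, 0.0, 1.0)
        seg1 = c * delta * ((A - s0) * (x**3 - 0.5 * x**4) - delta * (0.75 * x**4 - 0.4 * x**5))
        seg2 = np.where(
            t > s0 + delta, 0.5 * c * ((A - s0 - delta) ** 2 - (A - t) ** 2), 0.0
        )
        return seg1 + seg2

    total = float(unscaled(A))
    alpha = 0.0 if total <= 0 else min(s_total / total, 1.0)
    return unscaled, alpha, s0, delta, A


def _smooth_stop(age, params: QEPSParams):
    unscaled, alpha, _, _, _ = _smooth_stop_pieces(params)
    return alpha * unscaled(age)


def _smooth_stop_velocity(age, params: QEPSParams):
    unscaled, alpha, s0, delta, A = _smooth_stop_pieces(params)
    a = np.asarray(age, dtype=float)
    x = np.clip((a - s0) / delta, 0.0, 1.0)
    ramp = 3.0 * x**2 - 2.0 * x**3
    return np.where(a < A, alpha * ramp * q_velocity(np.minimum(a, A), params), 0.0)


def s_function(age, params: QEPSParams):
    """Stop component (cm): basic growth forgone after puberty winds down."""
    mode = params.shape.stop_mode
    a = np.asarray(age, dtype=float)
    if mode == "none":
        val = np.zeros_like(a) + 0.0 * q_function(a, params)  # domain check
    elif mode == "hard_cap":
        capped = np.minimum(a, params.age_p95_years)
        val = q_function(a, params) - q_function(capped, params)
    else:
        val = 0.0 * q_function(a, params) + _smooth_stop(a, params)  # domain check
    return _scalar_like(val, age)


def qs_function(age, params: QEPSParams):
    """Stopped basic growth Q - S (cm)."""
    mode = params.shape.stop_mode
    a = np.asarray(age, dtype=float)
    if mode == "none":
        val = q_function(a, params)
    elif mode == "hard_cap":
        val = q_function(np.minimum(a, params.age_p95_years), params)
    else:
        val = q_function(a, params) - _smooth_stop(a, params)
    return _scalar_like(val, age)


def qs_velocity(age, params: QEPSParams):
    mode = params.shape.stop_mode
    a = np.asarray(age, dtype=float)
    if mode == "none":
        vel = q_velocity(a, params)
    elif mode == "hard_cap":
        vel = np.where(a < params.age_p95_years, q_velocity(a, params), 0.0)
    else:
        vel = q_velocity(a, params) - _smooth_stop_velocity(a, params)
    return _scalar_like(vel, age)


def total_height(age, params: QEPSParams):
    """Modelled height T = E + QS + P (cm)."""
    a = np.asarray(age, dtype=float)
    val = e_function(a, params) + qs_function(a, params) + p_function(a, params)
    return _scalar_like(val, age)


def total_velocity(age, params: QEPSParams):
    """Analytic height velocity dT/dage (cm/year)."""
    a = np.asarray(age, dtype=float)
    vel = e_velocity(a, params) + qs_velocity(a, params) + p_velocity(a, params)
    return _scalar_like(vel, age)


def pubertal_p_gain(p_max_cm: float) -> float:
    """Height gained from the puberty-specific component between its 5%
    milestone and completion: 0.95 of the component amplitude."""
    return 0.95 * p_max_cm


def stopped_basic_max(
    q_max_cm: float, age_p95_years: float, shape: ShapeConstants
) -> float:
    """Asymptote of the stopped basic component QS: the quadratic evaluated
    where the stop takes full effect (the 95% pubertal milestone)."""
    A, t0 = shape.age_qmax_years, shape.t0_years
    if age_p95_years >= A:  # puberty ends after basic growth completes
        return q_max_cm
    return q_max_cm * (1.0 - ((A - age_p95_years) / (A - t0)) ** 2)


def adult_height_from_components(
    e_max_cm: float,
    q_max_cm: float,
    p_max_cm: float,
    age_p95_years: float,
    shape: ShapeConstants | None = None,
) -> float:
    """Adult height T_max = E_max + QS_max + P_max from component maxima."""
    shape = shape if shape is not None else ShapeConstants()
    return e_max_cm + stopped_basic_max(q_max_cm, age_p95_years, shape) + p_max_cm


@dataclass
class DerivedGrowthVariables:
    """Milestones, maxima and gains extracted from one parameter set.

    SDS-denominated fields are ``None`` until filled by a reference model.
    """

    e_max_cm: float
    q_max_cm: float
    p_max_cm: float
    qe_max_cm: float
    qs_max_cm: float
    t_max_cm: float
    age_e99_years: float
    age_p1_years: float
    age_p5_years: float
    age_p50_years: float
    age_p95_years: float
    age_p99_years: float
    age_tphv_years: float
    age_s0_years: float
    childhood_duration_years: float
    t_pubgain_p5_95_cm: float
    qes_pubgain_p5_95_cm: float
    p_pubgain_cm: float
    t_max_sds: float | None = None
    diff_mph_tmax_sds: float | None = None

    FIELDS = (
        "e_max_cm",
        "q_max_cm",
        "p_max_cm",
        "qe_max_cm",
        "qs_max_cm",
        "t_max_cm",
        "age_e99_years",
        "age_p1_years",
        "age_p5_years",
        "age_p50_years",
        "age_p95_years",
        "age_p99_years",
        "age_tphv_years",
        "age_s0_years",
        "childhood_duration_years",
        "t_pubgain_p5_95_cm",
        "qes_pubgain_p5_95_cm",
        "p_pubgain_cm",
        "t_max_sds",
        "diff_mph_tmax_sds",
    )

    def as_dict(self) -> dict:
        return {name: getattr(self, name) for name in self.FIELDS}


def _solve_fraction(func, target, lo, hi, expand=0.5, max_expand=20):
    """Bracketed root of ``func(x) - target`` with bracket growth."""
    for _ in range(max_expand):
        flo, fhi = func(lo) - target, func(hi) - target
        if flo == 0.0:
            return lo
        if fhi == 0.0:
            return hi
        if flo * fhi < 0:
            return brentq(lambda x: func(x) - target, lo, hi, xtol=1e-9)
        lo, hi = lo - expand, hi + expand
    raise ComputationError(
        f"no sign change bracketing target {target} in [{lo}, {hi}]"
    )


def _age_p_fraction(fraction: float, params: QEPSParams) -> float:
    """Age at which ``fraction`` of the pubertal amplitude is attained."""
    guess = params.age_p50_years + params.shape.offset_for(fraction) * params.p_timescale
    lo = guess - 0.3 * params.p_timescale
    hi = guess + 0.3 * params.p_timescale
    return _solve_fraction(
        lambda a: p_function(a, params), fraction * params.p_max, lo, hi
    )


def derive_variables(params: QEPSParams) -> DerivedGrowthVariables:
    """Extract all derived growth variables from a parameter set.

    Milestone ages solve the component-fraction equations numerically
    (bracketed, 1e-9 y tolerance); the age at peak height velocity maximises
    the analytic velocity of the total curve near mid-puberty.
    """
    shape = params.shape
    tau = shape.e_tau_ref * params.e_timescale
    e99_guess = shape.t0_years + _LN100 * tau
    age_e99 = _solve_fraction(
        lambda a: e_function(a, params),
        0.99 * params.e_max,
        e99_guess - 0.2,
        e99_guess + 0.2,
    )

    age_p = {q: _age_p_fraction(q, params) for q in (0.01, 0.05, 0.5, 0.95, 0.99)}

    res = minimize_scalar(
        lambda a: -total_velocity(a, params),
        bounds=(params.age_p50_years - 4.0, params.age_p50_years + 4.0),
        method="bounded",
        options={"xatol": 1e-6},
    )
    if not res.success:
        raise ComputationError(f"peak-velocity search failed: {res.message}")
    age_tphv = float(res.x)

    if shape.stop_mode == "none":
        qs_max = params.q_max
        age_s0 = float("inf")
    else:
        qs_max = stopped_basic_max(params.q_max, age_p[0.95], shape)
        age_s0 = (
            age_p[0.95] if shape.stop_mode == "hard_cap" else params.age_p50_years
        )
    t_max = params.e_max + qs_max + params.p_max
    p_gain = pubertal_p_gain(params.p_max)
    qes_gain = qs_max - qs_function(age_p[0.05], params)

    return DerivedGrowthVariables(
        e_max_cm=params.e_max,
        q_max_cm=params.q_max,
        p_max_cm=params.p_max,
        qe_max_cm=params.e_max + params.q_max,
        qs_max_cm=qs_max,
        t_max_cm=t_max,
        age_e99_years=age_e99,
        age_p1_years=age_p[0.01],
        age_p5_years=age_p[0.05],
        age_p50_years=age_p[0.5],
        age_p95_years=age_p[0.95],
        age_p99_years=age_p[0.99],
        age_tphv_years=age_tphv,
        age_s0_years=age_s0,
        childhood_duration_years=age_p[0.05] - age_e99,
        t_pubgain_p5_95_cm=qes_gain + p_gain,
        qes_pubgain_p5_95_cm=qes_gain,
        p_pubgain_cm=p_gain,
    )
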