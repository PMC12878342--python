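import numpy as np
import pytest

from qepsgrowth.core import QEPSParams, ShapeConstants
from qepsgrowth.fitting import FitConfig, fit_cohort
from qepsgrowth.reference import build_reference
from qepsgrowth.simulate import get_preset, generate_cohort


REFERENCE_MEANS = dict(
    e_max=65.1, q_max=104.1, p_max=17.4, e_timescale=1.01, p_timescale=1.01,
    age_p50=13.8,
)


@pytest.fixture(scope="session")
def ref_params() -> QEPSParams:
    """Healthy-reference group-mean parameter set."""
    return QEPSParams(65.1, 104.1, 17.4, 1.01, 1.01, 13.8)


@pytest.fixture(scope="session")
def ks_params() -> QEPSParams:
    """Clinical pubertal-subgroup group-mean parameter set."""
    return QEPSParams(63.4, 111.5, 17.6, 0.96, 1.00, 13.3)


def random_params(rng: np.random.Generator, shape: ShapeConstants | None = None):
    """A random valid parameter set spanning the admissible box broadly."""
    return QEPSParams(
        e_heightscale_cm=rng.uniform(40.0, 90.0),
        q_heightscale_cm=rng.uniform(70.0, 140.0),
        p_heightscale_cm=rng.uniform(4.0, 30.0),
        e_timescale=rng.uniform(0.45, 2.4),
        p_timescale=rng.uniform(0.45, 2.4),
        age_p50_years=rng.uniform(8.5, 19.0),
        shape=shape if shape is not None else ShapeConstants(),
    )


def cohort_like_params(rng: np.random.Generator):
    """A random parameter set near the reference cohort moments (±2.5 SD)."""
    return QEPSParams(
        e_heightscale_cm=65.1 + rng.uniform(-2.5, 2.5) * 2.9,
        q_heightscale_cm=104.1 + rng.uniform(-2.5, 2.5) * 8.0,
        p_heightscale_cm=17.4 + rng.uniform(-2.5, 2.5) * 3.6,
        e_timescale=1.01 + rng.uniform(-2.5, 2.5) * 0.09,
        p_timescale=1.01 + rng.uniform(-2.5, 2.5) * 0.05,
        age_p50_years=13.8 + rng.uniform(-2.5, 2.5) * 1.0,
    )


@pytest.fixture(scope="session")
def small_reference_cohort():
    """Forty simulated reference individuals plus their generating truth."""
    spec = get_preset("reference", 40, seed=11)
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def small_reference_fits(small_reference_cohort):
    records, _ = small_reference_cohort
    return fit_cohort(records, FitConfig(n_starts=3, seed=5))


@pytest.fixture(scope="session")
def small_reference_model(small_reference_fits, small_reference_cohort):
    records, _ = small_reference_cohort
    return build_reference(small_reference_fits, records)
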