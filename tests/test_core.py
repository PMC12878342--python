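import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from qepsgrowth import core
from qepsgrowth.core import (
    DomainError,
    QEPSParams,
    ShapeConstants,
    adult_height_from_components,
    calibrate_e_tau,
    calibrate_p_offsets,
    derive_variables,
    e_function,
    p_function,
    pubertal_p_gain,
    q_function,
    qs_function,
    s_function,
    stopped_basic_max,
    t0_from_gestational_age,
    total_height,
    total_velocity,
)

from conftest import random_params


T0 = t0_from_gestational_age(None)
A_QMAX = 21.5


def closed_form_q(age, q_max, t0=T0, a=A_QMAX):
    """Independent oracle: direct evaluation of the quadratic."""
    return q_max * (1.0 - ((a - age) / (a - t0)) ** 2)


class TestShapeConstants:
    def test_default_t0_matches_term_pregnancy(self):
        assert T0 == pytest.approx(-0.6133, abs=5e-4)
        assert T0 < 0

    def test_t0_shifts_with_gestational_age(self):
        preterm = t0_from_gestational_age(32.0)
        assert preterm > T0  # origin closer to birth for preterm
        assert t0_from_gestational_age(40.0) == T0

    def test_implausible_ga_rejected(self):
        with pytest.raises(ValueError):
            t0_from_gestational_age(10.0)

    def test_female_constants(self):
        shp = ShapeConstants.female()
        assert shp.age_qmax_years == 19.1
        assert ShapeConstants.male().age_qmax_years == 21.5

    def test_offsets_strictly_increasing_and_median_zero(self):
        shp = ShapeConstants()
        offs = dict(shp.p_quantile_offsets)
        assert offs[0.5] == 0.0
        qs = sorted(offs)
        vals = [offs[q] for q in qs]
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_invalid_constants_rejected(self):
        with pytest.raises(ValueError):
            ShapeConstants(t0_years=0.1)
        with pytest.raises(ValueError):
            ShapeConstants(age_qmax_years=17.0)
        with pytest.raises(ValueError):
            ShapeConstants(stop_mode="bogus")
        with pytest.raises(ValueError):
            ShapeConstants(p_quantile_offsets=((0.05, 1.0), (0.5, 0.0), (0.95, 2.0)))

    def test_e_tau_calibration(self):
        tau = calibrate_e_tau(1.88, 1.01, T0)
        assert tau == pytest.approx((1.88 - T0) / (math.log(100) * 1.01))
        assert ShapeConstants().e_tau_ref == pytest.approx(tau)

    def test_p_offset_calibration(self):
        offs = calibrate_p_offsets(13.8, {0.05: 11.8, 0.95: 16.1}, 1.01)
        assert offs[0.5] == 0.0
        assert offs[0.05] == pytest.approx(-2.0 / 1.01)
        assert offs[0.95] == pytest.approx(2.3 / 1.01)


class TestParams:
    def test_invariant_violations(self):
        with pytest.raises(ValueError):
            QEPSParams(-1.0, 104.1, 17.4, 1.0, 1.0, 13.8)
        with pytest.raises(ValueError):
            QEPSParams(65.1, 104.1, 17.4, 0.3, 1.0, 13.8)
        with pytest.raises(ValueError):
            QEPSParams(65.1, 104.1, 17.4, 1.0, 1.0, 21.0)

    def test_amplitudes_are_asymptotes(self, ref_params):
        assert ref_params.e_max == ref_params.e_heightscale_cm
        assert ref_params.q_max == ref_params.q_heightscale_cm
        assert ref_params.p_max == ref_params.p_heightscale_cm

    def test_array_roundtrip(self, ref_params):
        again = QEPSParams.from_array(ref_params.as_array(), ref_params.shape)
        assert np.allclose(again.as_array(), ref_params.as_array())


class TestQFunction:
    def test_zero_at_origin(self, ref_params):
        assert q_function(T0, ref_params) == pytest.approx(0.0, abs=1e-12)

    def test_vertex_value(self, ref_params):
        assert q_function(21.5, ref_params) == pytest.approx(104.1)

    def test_value_at_birth(self, ref_params):
        # oracle: direct evaluation of the closed form
        assert closed_form_q(0.0, 104.1) == pytest.approx(5.6942, abs=1e-4)
        assert q_function(0.0, ref_params) == pytest.approx(5.6942, abs=1e-4)

    def test_domain_error(self, ref_params):
        with pytest.raises(DomainError):
            q_function(T0 - 0.01, ref_params)

    def test_concave_increasing(self, ref_params):
        ages = np.linspace(T0, 21.5, 500)
        q = q_function(ages, ref_params)
        dq = np.diff(q)
        assert np.all(dq > 0)
        assert np.all(np.diff(dq) < 1e-12)  # concave

    def test_velocity_declines_linearly_to_zero(self, ref_params):
        ages = np.linspace(0.0, 21.5, 100)
        v = core.q_velocity(ages, ref_params)
        assert v[-1] == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(np.diff(v) / np.diff(ages), (v[1] - v[0]) / (ages[1] - ages[0]))


class TestEFunction:
    def test_zero_at_origin(self, ref_params):
        assert e_function(T0, ref_params) == pytest.approx(0.0, abs=1e-12)

    def test_saturates(self, ref_params):
        assert e_function(18.0, ref_params) == pytest.approx(65.1, abs=1e-6)

    def test_reference_calibration_anchor(self, ref_params):
        # 99% of the amplitude at 1.88 postnatal years with timescale 1.01
        assert e_function(1.88, ref_params) == pytest.approx(0.99 * 65.1, abs=1e-9)

    def test_domain_error(self, ref_params):
        with pytest.raises(DomainError):
            e_function(T0 - 1.0, ref_params)


class TestPFunction:
    def test_half_amplitude_at_median(self, ref_params):
        assert p_function(13.8, ref_params) == pytest.approx(0.5 * 17.4, abs=1e-9)

    def test_onset_age_for_clinical_means(self, ks_params):
        # 5% milestone at mid-puberty 13.3 with unit timescale -> 11.3 y
        age_p5 = derive_variables(ks_params).age_p5_years
        assert age_p5 == pytest.approx(11.3, abs=0.05)

    def test_onset_to_end_span_at_unit_timescale(self):
        p = QEPSParams(65.1, 104.1, 17.4, 1.01, 1.0, 13.8)
        d = derive_variables(p)
        assert d.age_p95_years - d.age_p5_years == pytest.approx(4.26, abs=0.05)

    def test_quantile_offsets_honoured(self, ref_params):
        d = derive_variables(ref_params)
        for frac, age in [(0.01, 10.8), (0.05, 11.8), (0.5, 13.8),
                          (0.95, 16.1), (0.99, 17.6)]:
            got = {0.01: d.age_p1_years, 0.05: d.age_p5_years,
                   0.5: d.age_p50_years, 0.95: d.age_p95_years,
                   0.99: d.age_p99_years}[frac]
            assert got == pytest.approx(age, abs=0.05)

    def test_shape_is_right_skewed_not_symmetric(self):
        shp = ShapeConstants()
        # upper half is wider than the lower half
        assert shp.offset_for(0.95) > -shp.offset_for(0.05)
        assert shp.offset_for(0.99) > -shp.offset_for(0.01)

    def test_monotone_sigmoid(self, ref_params):
        ages = np.linspace(0.0, 25.0, 2000)
        p = p_function(ages, ref_params)
        assert np.all(np.diff(p) >= 0)
        assert p[0] == pytest.approx(0.0, abs=1e-12)
        assert p[-1] == pytest.approx(17.4, abs=1e-9)


class TestSFunction:
    def test_zero_before_onset(self, ref_params):
        d = derive_variables(ref_params)
        assert s_function(d.age_s0_years - 1.0, ref_params) == pytest.approx(0.0, abs=1e-12)

    def test_stopped_total_reference(self):
        # oracle: closed form Q_max * ((A - AgeP95) / (A - t0))**2
        s_total = 104.1 * ((21.5 - 16.1) / (21.5 - T0)) ** 2
        assert s_total == pytest.approx(6.21, abs=0.01)
        got = 104.1 - stopped_basic_max(104.1, 16.1, ShapeConstants())
        assert got == pytest.approx(s_total, abs=1e-9)

    def test_stopped_total_clinical(self):
        s_total = 111.5 * ((21.5 - 15.6) / (21.5 - T0)) ** 2
        assert s_total == pytest.approx(7.94, abs=0.01)
        got = 111.5 - stopped_basic_max(111.5, 15.6, ShapeConstants())
        assert got == pytest.approx(s_total, abs=1e-9)

    def test_qs_non_decreasing_both_modes(self, ref_params):
        for mode in ("hard_cap", "smooth"):
            p = QEPSParams(65.1, 104.1, 17.4, 1.01, 1.01, 13.8,
                           shape=ShapeConstants.male(stop_mode=mode))
            ages = np.linspace(T0, 30.0, 3000)
            assert np.all(np.diff(qs_function(ages, p)) >= -1e-10), mode

    def test_s_non_decreasing(self, ref_params):
        ages = np.linspace(T0, A_QMAX, 2000)
        assert np.all(np.diff(s_function(ages, ref_params)) >= -1e-10)
        smooth = QEPSParams(65.1, 104.1, 17.4, 1.01, 1.01, 13.8,
                            shape=ShapeConstants.male(stop_mode="smooth"))
        assert np.all(np.diff(s_function(ages, smooth)) >= -1e-10)

    def test_smooth_mode_same_asymptote(self):
        hard = QEPSParams(65.1, 104.1, 17.4, 1.01, 1.01, 13.8)
        smooth = QEPSParams(65.1, 104.1, 17.4, 1.01, 1.01, 13.8,
                            shape=ShapeConstants.male(stop_mode="smooth"))
        assert derive_variables(smooth).t_max_cm == pytest.approx(
            derive_variables(hard).t_max_cm, abs=1e-6
        )
        # but the smooth ramp starts at mid-puberty
        assert derive_variables(smooth).age_s0_years == pytest.approx(13.8)
        assert derive_variables(hard).age_s0_years == pytest.approx(16.1, abs=0.05)


class TestTotalHeight:
    def test_zero_at_origin(self, ref_params):
        assert total_height(T0, ref_params) == pytest.approx(0.0, abs=1e-9)

    def test_decomposition_with_stop_disabled(self):
        p = QEPSParams(65.1, 104.1, 1e-6, 1.01, 1.01, 13.8,
                       shape=ShapeConstants.male(stop_mode="none"))
        assert total_height(60.0, p) == pytest.approx(65.1 + 104.1, abs=1e-5)
        d = derive_variables(p)
        assert d.t_max_cm == pytest.approx(65.1 + 104.1 + 1e-6)

    def test_adult_height_reference_means(self, ref_params):
        d = derive_variables(ref_params)
        assert d.t_max_cm == pytest.approx(180.4, abs=0.1)
        assert abs(d.t_max_cm - 180.5) < 0.5

    def test_adult_height_from_components_helper(self):
        t = adult_height_from_components(65.1, 104.1, 17.4, 16.1)
        assert abs(t - 180.5) < 0.5

    def test_limit_is_t_max(self, ref_params):
        d = derive_variables(ref_params)
        assert total_height(80.0, ref_params) == pytest.approx(d.t_max_cm, abs=1e-9)


class TestDeriveVariables:
    def test_pubertal_gain_convention(self):
        # printed group means reproduce the printed total gains exactly
        assert round(16.2 + pubertal_p_gain(17.6), 1) == 32.9
        assert round(14.1 + pubertal_p_gain(17.4), 1) == 30.6

    def test_gain_additivity(self, ref_params):
        d = derive_variables(ref_params)
        assert d.t_pubgain_p5_95_cm == pytest.approx(
            d.qes_pubgain_p5_95_cm + d.p_pubgain_cm, abs=1e-9
        )

    def test_childhood_duration_reference(self, ref_params):
        d = derive_variables(ref_params)
        assert d.age_p5_years - d.age_e99_years == pytest.approx(9.9, abs=0.05)
        assert d.childhood_duration_years == pytest.approx(
            d.age_p5_years - d.age_e99_years
        )

    def test_age_e99_scales_with_timescale(self):
        p = QEPSParams(63.3, 110.9, 17.6, 0.96, 1.0, 13.3)
        assert derive_variables(p).age_e99_years == pytest.approx(1.76, abs=0.01)

    def test_milestone_ordering(self, ref_params):
        d = derive_variables(ref_params)
        assert (
            d.age_p1_years < d.age_p5_years < d.age_p50_years
            < d.age_p95_years < d.age_p99_years
        )
        assert d.age_e99_years < d.age_p5_years

    def test_qe_max(self, ref_params):
        d = derive_variables(ref_params)
        assert d.qe_max_cm == pytest.approx(65.1 + 104.1)
        assert d.qs_max_cm <= d.q_max_cm

    def test_sds_fields_unset(self, ref_params):
        d = derive_variables(ref_params)
        assert d.t_max_sds is None and d.diff_mph_tmax_sds is None


class TestProperties:
    N_SETS = 250  # full 1000-set sweeps live in the acceptance suite

    def test_additivity_exact(self):
        rng = np.random.default_rng(42)
        ages = np.linspace(T0, 25.0, 257)
        for _ in range(self.N_SETS):
            p = random_params(rng)
            lhs = total_height(ages, p)
            rhs = (
                e_function(ages, p)
                + q_function(ages, p)
                - s_function(ages, p)
                + p_function(ages, p)
            )
            assert np.max(np.abs(lhs - rhs)) < 1e-10

    def test_conservation(self):
        rng = np.random.default_rng(43)
        for _ in range(self.N_SETS):
            p = random_params(rng)
            d = derive_variables(p)
            assert d.t_max_cm == pytest.approx(
                d.e_max_cm + d.qs_max_cm + d.p_max_cm, abs=1e-6
            )

    def test_monotone_total(self):
        rng = np.random.default_rng(44)
        for _ in range(self.N_SETS):
            p = random_params(rng)
            ages = np.arange(p.shape.t0_years, 25.0, 0.01)
            assert np.all(np.diff(total_height(ages, p)) >= -1e-10)

    def test_milestones_match_grid_scan(self):
        rng = np.random.default_rng(45)
        for _ in range(60):
            p = random_params(rng)
            d = derive_variables(p)
            lo = p.age_p50_years - 4.5 * p.p_timescale
            grid = np.arange(lo, p.age_p50_years + 4.6 * p.p_timescale, 1e-4)
            pv = p_function(grid, p)
            for frac, got in [(0.05, d.age_p5_years), (0.95, d.age_p95_years)]:
                idx = int(np.searchsorted(pv, frac * p.p_max))
                assert abs(grid[idx] - got) < 1e-3

    def test_phv_before_mid_puberty(self):
        rng = np.random.default_rng(46)
        for _ in range(self.N_SETS):
            p = random_params(rng)
            d = derive_variables(p)
            assert d.age_tphv_years < d.age_p50_years

    def test_phv_near_printed_reference_value(self, ref_params):
        d = derive_variables(ref_params)
        assert d.age_p50_years - d.age_tphv_years < 0.5
        assert d.age_tphv_years < d.age_p50_years

    def test_plateau_after_growth_ends(self):
        rng = np.random.default_rng(47)
        for _ in range(self.N_SETS):
            p = random_params(rng)
            d = derive_variables(p)
            ages = d.age_p99_years + 1.0 + np.linspace(0.0, 5.0, 50)
            assert np.all(total_velocity(ages, p) < 0.05)

    @settings(max_examples=60, deadline=None)
    @given(
        e=st.floats(30.0, 95.0),
        q=st.floats(60.0, 150.0),
        pm=st.floats(2.0, 35.0),
        ets=st.floats(0.45, 2.45),
        pts=st.floats(0.45, 2.45),
        p50=st.floats(8.2, 19.5),
    )
    def test_conservation_and_ordering_hypothesis(self, e, q, pm, ets, pts, p50):
        p = QEPSParams(e, q, pm, ets, pts, p50)
        d = derive_variables(p)
        assert d.t_max_cm == pytest.approx(
            d.e_max_cm + d.qs_max_cm + d.p_max_cm, abs=1e-6
        )
        assert d.age_p1_years < d.age_p5_years < d.age_p50_years
        assert d.age_p50_years < d.age_p95_years < d.age_p99_years
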