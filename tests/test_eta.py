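import math

import numpy as np
import pytest
from hypothesis import assume, given, settings, strategies as st
from scipy.optimize import brentq

from photokin.errors import DegenerateSystemError, ValidationError
from photokin.eta import (
    EtaParams,
    alpha1,
    alpha2,
    concentration_at_time,
    eta_of_t,
    half_life,
    initial_velocity,
    k_eta_from_attributes,
    params_from_system,
    photokinetic_factor,
    total_absorbance,
    validity_check,
)
from photokin.spectra import ReactorGeometry

from conftest import line_lamp, toy_species


def bisect_concentration(t, params, xtol=1e-280):
    """Independent inversion of the implicit integrated law by brentq."""

    def f(c):
        return (c - params.C0) + params.alpha2 * math.log(c / params.C0) + params.k_eta * t

    return brentq(f, 1e-280 * params.C0, params.C0, xtol=xtol, rtol=8.9e-16)


@pytest.fixture(scope="module")
def params():
    return EtaParams(alpha1=1.2e-6, alpha2=2e-5, k_eta=1e-7, C0=1e-4)


class TestTotalAbsorbance:
    def test_zero_concentrations(self, geometry):
        sp = toy_species([300.0, 301.0], [1e4, 2e4], [1e3, 2e3], [0.3, 0.3])
        assert total_absorbance(sp, geometry, 0.0, 0.0) == 0.0

    def test_two_wavelength_hand_value(self, geometry):
        # l=1: (1e4*1e-5 + 1e3*2e-5) + (2e4*1e-5 + 2e3*2e-5) = 0.12 + 0.24
        sp = toy_species([300.0, 301.0], [1e4, 2e4], [1e3, 2e3], [0.3, 0.3])
        assert total_absorbance(sp, geometry, 1e-5, 2e-5) == pytest.approx(0.36)

    def test_linear_in_CA(self, geometry):
        sp = toy_species([300.0, 301.0], [1e4, 2e4], [1e3, 2e3], [0.3, 0.3])
        a1 = total_absorbance(sp, geometry, 1e-5, 2e-5)
        a2_ = total_absorbance(sp, geometry, 3e-5, 2e-5)
        a0 = total_absorbance(sp, geometry, 0.0, 2e-5)
        assert a2_ - a0 == pytest.approx(3 * (a1 - a0))

    def test_negative_concentration_rejected(self, geometry):
        sp = toy_species([300.0], [1e4], [1e3], [0.3])
        with pytest.raises(ValidationError):
            total_absorbance(sp, geometry, -1e-6, 0.0)


class TestPhotokineticFactor:
    def test_reference_values(self):
        assert photokinetic_factor(1.0) == pytest.approx(0.9, rel=0, abs=1e-15)
        assert photokinetic_factor(1e-12) == pytest.approx(math.log(10.0), rel=1e-9)
        assert photokinetic_factor(3.0) == pytest.approx(0.333, rel=1e-3)
        assert photokinetic_factor(3.0, reduced=True) == pytest.approx(1 / 3)

    def test_full_vs_reduced_gap_small_at_high_absorbance(self):
        full, red = photokinetic_factor(3.0), photokinetic_factor(3.0, reduced=True)
        assert abs(red - full) / red == pytest.approx(1e-3, rel=0.01)

    def test_reduced_rejects_zero(self):
        with pytest.raises(ZeroDivisionError):
            photokinetic_factor(0.0, reduced=True)


class TestAlphaCoefficients:
    """Mixing coefficients from published window-summed absorptivities
    of dacarbazine and its photoproduct."""

    SUM_A, SUM_B = 1_150_028.96, 344_785.15

    def _species(self):
        return toy_species([330.0], [self.SUM_A], [self.SUM_B], [0.3])

    def test_alpha1_dbz_totals(self, geometry):
        assert alpha1(self._species(), geometry) == pytest.approx(1.2419e-6, rel=1e-4)

    def test_alpha2_dbz_totals(self):
        assert alpha2(self._species(), 5.41e-5) == pytest.approx(2.3165e-5, rel=1e-4)

    def test_transparent_photoproduct_zeroes_alpha2(self):
        sp = toy_species([330.0], [1e4], [0.0], [0.3])
        assert alpha2(sp, 1e-4) == 0.0

    def test_equal_totals_raise_degenerate(self, geometry):
        sp = toy_species([330.0], [1e4], [1e4], [0.3])
        with pytest.raises(DegenerateSystemError):
            alpha1(sp, geometry)


class TestKEtaFromAttributes:
    def test_single_wavelength_value(self):
        sp = toy_species([254.0], [1e4], [0.0], [0.5])
        lamp = line_lamp(254.0, 1e-5)
        assert k_eta_from_attributes(sp, lamp) == pytest.approx(5e-6)

    def test_homogeneous_in_flux(self):
        sp = toy_species([254.0], [1e4], [2e3], [0.5])
        k1 = k_eta_from_attributes(sp, line_lamp(254.0, 1e-5))
        k2 = k_eta_from_attributes(sp, line_lamp(254.0, 2e-5))
        assert k2 == pytest.approx(2 * k1, rel=1e-14)

    def test_independent_of_C0_and_path(self, default_system):
        """k_eta depends on spectra and lamp only, not on C0 or l_irr."""
        sys_ = default_system
        for c0 in (1.5e-5, 10.5e-5):
            for l in (0.5, 2.0):
                p = params_from_system(
                    sys_.species, sys_.lamp, ReactorGeometry(l_irr_cm=l), c0
                )
                assert p.k_eta == pytest.approx(sys_.params.k_eta, rel=1e-12)


class TestEtaOfT:
    def test_identity_at_C0(self, params):
        assert eta_of_t(params.C0, params) == 0.0

    def test_zeroth_order_limit(self):
        p = EtaParams(alpha1=1e-6, alpha2=0.0, k_eta=1e-7, C0=1e-4)
        assert eta_of_t(6e-5, p) == pytest.approx(6e-5 - 1e-4)

    def test_hand_value(self, params):
        # (6.016e-5 - 1e-4) + 2e-5*ln(0.6016) = -5.000e-5
        assert eta_of_t(6.016e-5, params) == pytest.approx(-5.000e-5, rel=1e-3)

    def test_monotone_decreasing_in_decreasing_C(self, params):
        c = np.linspace(params.C0, 1e-6, 50)
        vals = eta_of_t(c, params)
        assert np.all(np.diff(vals) < 0)
        assert np.all(vals <= 0)

    def test_rejects_nonpositive(self, params):
        with pytest.raises(ValidationError):
            eta_of_t(0.0, params)


class TestConcentrationAtTime:
    def test_t0_returns_C0(self, params):
        assert concentration_at_time(0.0, params) == pytest.approx(params.C0, rel=1e-14)

    def test_reference_inversion(self, params):
        # frozen from bisection of the implicit law at 1e-12 tolerance
        assert concentration_at_time(500.0, params) == pytest.approx(6.016244e-5, rel=1e-6)

    def test_monotone_never_negative_decays_to_zero(self, params):
        t = np.geomspace(1.0, 1e7, 200)
        c = concentration_at_time(t, params)
        assert np.all(np.diff(c) <= 0)
        assert np.all(c >= 0)
        assert c[-1] < 1e-9 * params.C0

    def test_negative_time_rejected(self, params):
        with pytest.raises(ValidationError):
            concentration_at_time(-1.0, params)

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(
        log_c0=st.floats(-6.0, -3.0),
        ratio=st.floats(1e-3, 50.0),
        log_k=st.floats(-9.0, -5.0),
        frac=st.floats(0.01, 6.0),
    )
    def test_closed_form_matches_bisection_everywhere(self, log_c0, ratio, log_k, frac):
        """Property: the Lambert-W inversion satisfies the implicit law to
        1e-10*C0 and agrees with independent root bracketing to 1e-10
        relative, across random valid parameter sets and times."""
        c0, k = 10.0**log_c0, 10.0**log_k
        p = EtaParams(alpha1=1e-6, alpha2=ratio * c0, k_eta=k, C0=c0)
        t = frac * half_life(p)
        # keep the exact solution representable in double precision:
        # ln(C/C0) <= (C0 - k*t)/alpha2 must stay above the underflow floor
        assume((c0 - k * t) / p.alpha2 > -600.0)
        c = concentration_at_time(t, p)
        residual = (c - c0) + p.alpha2 * math.log(c / c0) + k * t
        assert abs(residual) <= 1e-10 * c0
        assert c == pytest.approx(bisect_concentration(t, p), rel=1e-10)


class TestHalfLife:
    def test_reference_value_and_consistency(self, params):
        t_half = half_life(params)
        assert t_half == pytest.approx(638.63, rel=1e-4)
        assert concentration_at_time(t_half, params) == pytest.approx(5e-5, rel=1e-10)

    def test_zeroth_order_limit(self):
        p = EtaParams(alpha1=1e-6, alpha2=0.0, k_eta=1e-7, C0=1e-4)
        assert half_life(p) == pytest.approx(0.5 * 1e-4 / 1e-7)

    def test_doubling_flux_halves_half_life(self, params):
        doubled = EtaParams(params.alpha1, params.alpha2, 2 * params.k_eta, params.C0)
        assert half_life(doubled) == pytest.approx(half_life(params) / 2)

    def test_requires_positive_k(self, params):
        with pytest.raises(ValidationError):
            half_life(EtaParams(params.alpha1, params.alpha2, 0.0, params.C0))


class TestInitialVelocity:
    def _setup(self, c0):
        sp = toy_species([330.0], [2e5], [4e4], [0.3])
        lamp = line_lamp(330.0, 1e-5)
        geom = ReactorGeometry()
        p = params_from_system(sp, lamp, geom, c0)
        return sp, geom, p

    def test_composition_of_parts(self, geometry):
        sp, geom, p = self._setup(1e-4)
        A0 = total_absorbance(sp, geom, p.C0, 0.0)
        expected = -p.C0 * p.k_eta * geom.l_irr_cm * (2e5 - 4e4) * photokinetic_factor(A0)
        assert initial_velocity(p, sp, geom) == pytest.approx(expected, rel=1e-14)

    def test_independent_of_C0_at_high_absorbance(self):
        # both starting absorbances exceed 3: |r0| values within 0.1%
        r = []
        for c0 in (2e-5, 4e-5):
            sp, geom, p = self._setup(c0)
            assert total_absorbance(sp, geom, c0, 0.0) > 3
            r.append(abs(initial_velocity(p, sp, geom)))
        assert abs(r[0] - r[1]) / r[0] < 1e-3

    def test_zero_flux_zero_velocity(self, geometry):
        sp = toy_species([330.0], [2e5], [4e4], [0.3])
        p = EtaParams(alpha1=6.25e-6, alpha2=2.5e-5, k_eta=0.0, C0=1e-4)
        assert initial_velocity(p, sp, geometry) == 0.0


class TestValidityCheck:
    def _species(self):
        return toy_species([330.0], [2e5], [4e4], [0.3])

    def test_high_absorbance_no_flag(self, geometry, params):
        rep = validity_check(self._species(), geometry, params, trace_end_absorbance=5.0)
        assert rep.ok

    def test_low_absorbance_flags_reduced_factor(self, geometry, params):
        rep = validity_check(self._species(), geometry, params, trace_end_absorbance=0.5)
        assert rep.reduced_factor_invalid and not rep.ok

    def test_c0_outside_linearity_flagged(self, geometry, params):
        rep = validity_check(
            self._species(), geometry, params, 5.0, linearity_range=(1.5e-5, 9e-5)
        )
        assert rep.c0_outside_linearity

    def test_inverted_absorptivities_flagged(self, geometry, params):
        sp = toy_species([330.0], [4e4], [2e5], [0.3])
        rep = validity_check(sp, geometry, params, 5.0)
        assert rep.nonpositive_delta_eps


class TestLimitingOrders:
    def test_transparent_photoproduct_linear_trace(self):
        """eps_B = 0 collapses the law to the zeroth-order form C0 - k*t."""
        p = EtaParams(alpha1=1e-6, alpha2=0.0, k_eta=1e-7, C0=1e-4)
        t = np.linspace(0, 900, 10)  # stays above C = C0/10
        np.testing.assert_allclose(concentration_at_time(t, p), 1e-4 - 1e-7 * t, rtol=1e-12)

    def test_first_order_limit_at_small_epsilon_gap(self):
        """As sum(eps_B) -> sum(eps_A) (relative gap 1e-3) the trace
        converges to the exponential C0*exp(-(k_eta/alpha2)*t) within 1%."""
        sum_a, gap = 1e6, 1e-3
        sp = toy_species([330.0], [sum_a], [sum_a * (1 - gap)], [0.3])
        lamp = line_lamp(330.0, 1e-5)
        c0 = 1e-4
        p = params_from_system(sp, lamp, ReactorGeometry(), c0)
        k1 = p.k_eta / p.alpha2  # first-order rate constant in the limit
        t = np.linspace(0, 3 / k1, 60)
        c = concentration_at_time(t, p)
        expected = c0 * np.exp(-k1 * t)
        assert np.max(np.abs(c - expected) / expected) < 0.01
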