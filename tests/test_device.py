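"""Unit and property tests for the bare-transistor physics."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from glucofet import (
    CONSTANTS,
    DerivedParams,
    DeviceGeometry,
    TransportParams,
    channel_current,
    derive_params,
    drain_current_bare,
    drift_velocity,
    electrostatic_capacitance,
    quantum_capacitance,
    saturation_drain_voltage,
    series_gate_capacitance,
)
from glucofet.exceptions import InvalidParameterError


def make_derived(beta=1.0, v_c=1.0):
    """DerivedParams with prescribed transport constants (capacitances inert)."""
    return DerivedParams(
        electrostatic_capacitance_per_length=2.0,
        quantum_capacitance_per_length=2.0,
        gate_capacitance_per_length=1.0,
        beta=beta,
        critical_voltage=v_c,
    )


class TestDriftVelocity:
    @pytest.mark.parametrize(
        "field,mu,e_c,expected",
        [
            (0.0, 0.05, 1e5, 0.0),  # zero field, zero velocity
            (1e5, 1.0, 1e5, 0.5e5),  # at E = E_c: half the asymptote mu*E_c
            (1e5, 0.1, 1e5, 5.0e3),  # frozen high-precision evaluation
        ],
    )
    def test_known_values(self, field, mu, e_c, expected):
        assert drift_velocity(field, mu, e_c) == pytest.approx(expected, rel=1e-12)

    def test_approaches_saturation_asymptote(self):
        mu, e_c = 0.08, 2e5
        assert drift_velocity(1e12, mu, e_c) == pytest.approx(mu * e_c, rel=1e-6)

    @given(st.floats(0.0, 1e8), st.floats(1e7, 1e8))
    def test_monotone_in_field(self, e1, e2):
        lo, hi = sorted((e1, e2))
        assert drift_velocity(lo, 0.1, 1e5) <= drift_velocity(hi, 0.1, 1e5)

    @pytest.mark.parametrize("mu,e_c", [(0.0, 1e5), (-1.0, 1e5), (0.1, 0.0), (0.1, -2.0)])
    def test_invalid_parameters(self, mu, e_c):
        with pytest.raises(InvalidParameterError):
            drift_velocity(1.0, mu, e_c)

    def test_negative_field_rejected(self):
        with pytest.raises(InvalidParameterError):
            drift_velocity(-1.0, 0.1, 1e5)


class TestCapacitances:
    def test_electrostatic_reference_value(self):
        # 1.5 nm tube on 100 um PET at eps_r = 3.3: ~14.7 aF/um
        c_e = electrostatic_capacitance(DeviceGeometry(1.5e-9, 50e-6, 100e-6, 3.3))
        assert c_e == pytest.approx(1.4694e-11, rel=5e-4)

    def test_electrostatic_monotone_in_thickness(self):
        thin = electrostatic_capacitance(DeviceGeometry(substrate_thickness=100e-6))
        thick = electrostatic_capacitance(DeviceGeometry(substrate_thickness=200e-6))
        assert thick < thin

    def test_electrostatic_linear_in_permittivity(self):
        base = electrostatic_capacitance(DeviceGeometry(relative_permittivity=3.3))
        doubled = electrostatic_capacitance(DeviceGeometry(relative_permittivity=6.6))
        assert doubled == pytest.approx(2.0 * base, rel=1e-12)

    def test_electrostatic_domain_guard(self):
        # 4H/d <= 1 is unphysical; rejected at geometry construction
        with pytest.raises(InvalidParameterError):
            DeviceGeometry(cnt_diameter=1e-6, substrate_thickness=2e-7)

    def test_quantum_capacitance_printed_value(self):
        # ~76.5 aF/um at v_F = 1e6 m/s (within 2%)
        c_q = quantum_capacitance(1.0e6)
        assert c_q * 1e12 == pytest.approx(76.5, rel=0.02)

    def test_quantum_capacitance_inverse_proportionality(self):
        assert quantum_capacitance(2e6) == pytest.approx(quantum_capacitance(1e6) / 2, rel=1e-12)

    def test_quantum_capacitance_identity_scaling(self):
        e, h = CONSTANTS.elementary_charge, CONSTANTS.planck_constant
        assert quantum_capacitance(2 * e * e / h) == pytest.approx(1.0, rel=1e-12)

    @given(st.floats(1e4, 1e8))
    def test_quantum_capacitance_product_constant(self, v_f):
        e, h = CONSTANTS.elementary_charge, CONSTANTS.planck_constant
        assert quantum_capacitance(v_f) * v_f == pytest.approx(2 * e * e / h, rel=1e-9)

    def test_series_halving_and_limits(self):
        assert series_gate_capacitance(2.0, 2.0) == 1.0
        assert series_gate_capacitance(1e12, 3.0) == pytest.approx(3.0, rel=1e-9)

    def test_series_reference_value(self):
        c = series_gate_capacitance(14.7e-12, 76.5e-12)
        assert c * 1e12 == pytest.approx(14.7 * 76.5 / (14.7 + 76.5), rel=1e-12)
        assert c * 1e12 == pytest.approx(12.33, rel=1e-3)

    @given(st.floats(1e-13, 1e-9), st.floats(1e-13, 1e-9))
    def test_series_symmetric_and_bounded(self, a, b):
        c = series_gate_capacitance(a, b)
        assert c == series_gate_capacitance(b, a)
        assert c < min(a, b)
        assert c <= max(a, b) / 2 * (1 + 1e-12)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(InvalidParameterError):
            quantum_capacitance(0.0)
        with pytest.raises(InvalidParameterError):
            series_gate_capacitance(0.0, 1.0)


class TestDeriveParams:
    def test_critical_voltage_inverse_in_mobility(self, geometry):
        base = derive_params(geometry, TransportParams(mobility=0.1))
        halved = derive_params(geometry, TransportParams(mobility=0.05))
        assert halved.critical_voltage == pytest.approx(2 * base.critical_voltage, rel=1e-12)

    def test_channel_length_scaling(self, transport):
        short = derive_params(DeviceGeometry(channel_length=50e-6), transport)
        long = derive_params(DeviceGeometry(channel_length=100e-6), transport)
        assert long.beta == pytest.approx(short.beta / 2, rel=1e-12)
        assert long.critical_voltage == pytest.approx(2 * short.critical_voltage, rel=1e-12)

    def test_series_bound_invariant(self, derived):
        assert derived.gate_capacitance_per_length < min(
            derived.electrostatic_capacitance_per_length,
            derived.quantum_capacitance_per_length,
        )


class TestSaturationDrainVoltage:
    def test_square_law_limit(self):
        assert saturation_drain_voltage(1.0, 1e9) == pytest.approx(1.0, rel=1e-6)

    def test_closed_form_value(self):
        assert saturation_drain_voltage(1.0, 1.0) == pytest.approx(math.sqrt(3) - 1, rel=1e-12)

    def test_off_state(self):
        assert saturation_drain_voltage(0.0, 1.0) == 0.0
        assert saturation_drain_voltage(-0.5, 1.0) == 0.0

    def test_agrees_with_grid_argmax(self, rng):
        # brute-force argmax of the unclamped numerator/denominator ratio
        for _ in range(20):
            v_gt = rng.uniform(0.1, 5.0)
            v_c = rng.uniform(0.05, 50.0)
            grid = np.linspace(0.0, v_gt, 20001)
            values = (2 * v_gt * grid - grid**2) / (1 + grid / v_c)
            v_star = grid[np.argmax(values)]
            assert abs(saturation_drain_voltage(v_gt, v_c) - v_star) <= grid[1] - grid[0]


class TestDrainCurrent:
    def test_zero_bias(self):
        assert channel_current(1.0, 0.0, 1.0, 1.0) == 0.0

    def test_hand_values(self):
        # beta=1, V_GT=1, V_D=0.5: numerator 0.75; with V_c=1 divide by 1.5
        assert channel_current(1.0, 0.5, 1.0, 1e12) == pytest.approx(0.75, rel=1e-9)
        assert channel_current(1.0, 0.5, 1.0, 1.0) == pytest.approx(0.5, rel=1e-12)

    def test_bare_wrapper_uses_overdrive(self):
        d = make_derived(beta=1.0, v_c=1.0)
        assert drain_current_bare(1.3, 0.5, d, 0.3) == pytest.approx(
            channel_current(1.0, 0.5, 1.0, 1.0), rel=1e-15
        )

    def test_off_below_threshold(self):
        d = make_derived()
        assert drain_current_bare(0.2, 0.5, d, 0.3) == 0.0
        assert drain_current_bare(0.3, 0.5, d, 0.3) == 0.0

    def test_negative_drain_voltage_rejected(self):
        with pytest.raises(InvalidParameterError):
            channel_current(1.0, -0.1, 1.0, 1.0)

    def test_continuity_at_clamp(self):
        v_gt, v_c, beta = 1.0, 1.0, 1.0
        v_sat = saturation_drain_voltage(v_gt, v_c)
        eps = 1e-9
        below = channel_current(v_gt, v_sat - eps, beta, v_c)
        above = channel_current(v_gt, v_sat + eps, beta, v_c)
        at = channel_current(v_gt, v_sat, beta, v_c)
        assert below == pytest.approx(at, rel=1e-8)
        assert above == at  # exactly held constant past the peak

    @given(
        st.floats(0.1, 5.0),
        st.floats(0.05, 50.0),
        st.floats(0.0, 10.0),
        st.floats(0.0, 10.0),
    )
    def test_nondecreasing_in_drain_voltage(self, v_gt, v_c, va, vb):
        lo, hi = sorted((va, vb))
        assert channel_current(v_gt, lo, 1.0, v_c) <= channel_current(v_gt, hi, 1.0, v_c) + 1e-15

    @given(st.floats(0.1, 5.0), st.floats(0.1, 5.0), st.floats(0.0, 0.7))
    def test_nondecreasing_in_gate_voltage(self, g1, g2, v_d):
        lo, hi = sorted((g1, g2))
        assert channel_current(lo, v_d, 1.0, 2.0) <= channel_current(hi, v_d, 1.0, 2.0) + 1e-15

    def test_square_law_limit(self):
        # V_c -> inf recovers beta*(2 V_GT V_D - V_D^2) below pinch-off
        v_gt, beta = 1.5, 2.0
        v_d = np.linspace(0.0, 1.2, 50)
        approx = channel_current(v_gt, v_d, beta, 1e6)
        exact = beta * (2 * v_gt * v_d - v_d**2)
        np.testing.assert_allclose(approx, exact, rtol=1e-4)

    def test_vectorized_matches_scalar(self):
        v_d = np.array([0.0, 0.2, 0.5, 3.0])
        vec = channel_current(1.0, v_d, 1.0, 1.0)
        scal = [channel_current(1.0, v, 1.0, 1.0) for v in v_d]
        np.testing.assert_array_equal(vec, scal)


class TestTypeInvariants:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"cnt_diameter": 0.0},
            {"channel_length": -1e-6},
            {"relative_permittivity": 0.0},
        ],
    )
    def test_geometry_rejects_nonpositive(self, kwargs):
        with pytest.raises(InvalidParameterError):
            DeviceGeometry(**kwargs)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"mobility": 0.0},
            {"saturation_velocity": -1.0},
            {"fermi_velocity": 0.0},
            {"threshold_voltage": float("nan")},
        ],
    )
    def test_transport_rejects_invalid(self, kwargs):
        with pytest.raises(InvalidParameterError):
            TransportParams(**kwargs)

    def test_derived_rejects_non_series_gate(self):
        with pytest.raises(InvalidParameterError):
            DerivedParams(2.0, 2.0, 3.0, 1.0, 1.0)
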