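"""Closed-form physics of the bare back-gated SWCNT field-effect transistor.

The channel is a single-wall carbon nanotube (1–2 nm diameter, ~50 um long)
lying on a PET polyester substrate that acts as the back-gate dielectric.
Transport is described by a charge-based velocity-saturation model: the
carrier drift velocity is mobility-limited at low field and saturates above a
critical field, which bends the I-V curve into saturation around the critical
voltage V_c = (v_sat / mu) * L.

The gate couples to the channel through two capacitances in series, both per
unit length of tube:

* the electrostatic capacitance of a wire over a ground plane,
  ``C_E = 2 pi eps / ln(4 H / d)``, and
* the quantum capacitance of the one-dimensional channel,
  ``C_Q = 2 e^2 / (h v_F)``, a density-of-states effect set by the electron
  Fermi velocity (about 77 aF/um at v_F = 1e6 m/s).

The drain current above threshold is

    I_D = beta * (2 V_GT V_D - V_D^2) / (1 + V_D / V_c),

with ``beta = mu C_G / (2 L)`` and gate overdrive ``V_GT = V_G - V_T``. The
expression is valid up to the saturation drain voltage and is held constant
beyond it (continuous clamp); sub-threshold conduction is not modelled
(V_GT <= 0 gives zero current). All quantities are strict SI internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .constants import CONSTANTS
from .exceptions import DomainError, InvalidParameterError

__all__ = [
    "DeviceGeometry",
    "TransportParams",
    "DerivedParams",
    "drift_velocity",
    "electrostatic_capacitance",
    "quantum_capacitance",
    "series_gate_capacitance",
    "derive_params",
    "saturation_drain_voltage",
    "drain_current_bare",
    "channel_current",
]


@dataclass(frozen=True)
class DeviceGeometry:
    """Geometry of the nanotube channel and its PET back-gate dielectric.

    Parameters
    ----------
    cnt_diameter : float
        Nanotube diameter ``d`` in metres (typical 1–2 nm).
    channel_length : float
        Source–drain channel length ``L`` in metres.
    substrate_thickness : float
        PET substrate thickness ``H`` in metres (the gate-dielectric span).
    relative_permittivity : float
        Dielectric constant of the substrate (3.3 for PET).
    """

    cnt_diameter: float = 1.5e-9
    channel_length: float = 50e-6
    substrate_thickness: float = 100e-6
    relative_permittivity: float = 3.3

    def __post_init__(self) -> None:
        for name in (
            "cnt_diameter",
            "channel_length",
            "substrate_thickness",
            "relative_permittivity",
        ):
            value = getattr(self, name)
            if not (math.isfinite(value) and value > 0):
                raise InvalidParameterError(f"{name} must be strictly positive, got {value!r}")
        if 4.0 * self.substrate_thickness / self.cnt_diameter <= 1.0:
            raise InvalidParameterError(
                "4*substrate_thickness/cnt_diameter must exceed 1 "
                "(electrostatic-capacitance logarithm would be nonpositive)"
            )


@dataclass(frozen=True)
class TransportParams:
    """Carrier-transport parameters of the channel.

    mobility (m^2/Vs), saturation_velocity and fermi_velocity (m/s),
    threshold_voltage (V). Defaults give a device with currents in the
    10 nA decade over a 0–0.7 V drain sweep.
    """

    mobility: float = 0.1
    saturation_velocity: float = 8.0e5
    fermi_velocity: float = 1.0e6
    threshold_voltage: float = 0.3

    def __post_init__(self) -> None:
        for name in ("mobility", "saturation_velocity", "fermi_velocity"):
            value = getattr(self, name)
            if not (math.isfinite(value) and value > 0):
                raise InvalidParameterError(f"{name} must be strictly positive, got {value!r}")
        if not math.isfinite(self.threshold_voltage):
            raise InvalidParameterError("threshold_voltage must be finite")


@dataclass(frozen=True)
class DerivedParams:
    """Derived electrostatics and transport constants.

    Capacitances are per unit tube length (F/m); ``beta`` is the current
    prefactor mu*C_G/(2L) in A/V^2; ``critical_voltage`` is
    V_c = (v_sat/mu)*L in volts.
    """

    electrostatic_capacitance_per_length: float
    quantum_capacitance_per_length: float
    gate_capacitance_per_length: float
    beta: float
    critical_voltage: float

    def __post_init__(self) -> None:
        for name in (
            "electrostatic_capacitance_per_length",
            "quantum_capacitance_per_length",
            "gate_capacitance_per_length",
            "beta",
            "critical_voltage",
        ):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be strictly positive")
        if self.gate_capacitance_per_length >= min(
            self.electrostatic_capacitance_per_length,
            self.quantum_capacitance_per_length,
        ):
            raise InvalidParameterError(
                "series gate capacitance must be below both of its components"
            )


def drift_velocity(field, mobility: float, critical_field: float):
    """Carrier drift velocity ``v = mu E / (1 + E/E_c)`` (m/s).

    Mobility-limited at low field, saturating towards ``mu * E_c`` as the
    field grows. Accepts scalar or array ``field`` (V/m, nonnegative).
    """
    if not mobility > 0:
        raise InvalidParameterError("mobility must be strictly positive")
    if not critical_field > 0:
        raise InvalidParameterError("critical_field must be strictly positive")
    field_arr = np.asarray(field, dtype=float)
    if np.any(field_arr < 0):
        raise InvalidParameterError("field must be nonnegative")
    out = mobility * field_arr / (1.0 + field_arr / critical_field)
    return out if out.ndim else float(out)


def electrostatic_capacitance(geometry: DeviceGeometry) -> float:
    """Electrostatic gate-coupling capacitance per unit length (F/m).

    Wire-over-plane form ``2 pi eps / ln(4 H / d)`` with eps the substrate
    permittivity; about 14.7 aF/um for a 1.5 nm tube on 100 um PET.
    """
    ratio = 4.0 * geometry.substrate_thickness / geometry.cnt_diameter
    if ratio <= 1.0:
        raise DomainError("4*H/d must exceed 1 for the log to be positive")
    eps = geometry.relative_permittivity * CONSTANTS.vacuum_permittivity
    return 2.0 * math.pi * eps / math.log(ratio)


def quantum_capacitance(fermi_velocity: float) -> float:
    """Quantum capacitance of the gated nanotube per unit length (F/m).

    ``C_Q = 2 e^2 / (h v_F)`` — the density-of-states capacitance of the two
    degenerate 1-D conduction channels. At v_F = 1e6 m/s this is ~77 aF/um.
    """
    if not fermi_velocity > 0:
        raise InvalidParameterError("fermi_velocity must be strictly positive")
    e = CONSTANTS.elementary_charge
    h = CONSTANTS.planck_constant
    return 2.0 * e * e / (h * fermi_velocity)


def series_gate_capacitance(c_electrostatic: float, c_quantum: float) -> float:
    """Series combination ``C_E C_Q / (C_E + C_Q)`` per unit length (F/m)."""
    if not c_electrostatic > 0 or not c_quantum > 0:
        raise InvalidParameterError("capacitances must be strictly positive")
    return c_electrostatic * c_quantum / (c_electrostatic + c_quantum)


def derive_params(geometry: DeviceGeometry, transport: TransportParams) -> DerivedParams:
    """Populate all derived constants from geometry and transport inputs."""
    c_e = electrostatic_capacitance(geometry)
    c_q = quantum_capacitance(transport.fermi_velocity)
    c_g = series_gate_capacitance(c_e, c_q)
    beta = transport.mobility * c_g / (2.0 * geometry.channel_length)
    v_c = (transport.saturation_velocity / transport.mobility) * geometry.channel_length
    return DerivedParams(
        electrostatic_capacitance_per_length=c_e,
        quantum_capacitance_per_length=c_q,
        gate_capacitance_per_length=c_g,
        beta=beta,
        critical_voltage=v_c,
    )


def saturation_drain_voltage(v_gt: float, v_c: float) -> float:
    """Drain voltage at which the clamped I-V law peaks.

    Maximising ``(2 V_GT V_D - V_D^2)/(1 + V_D/V_c)`` over V_D gives

        V_Dsat = V_c * (sqrt(1 + 2 V_GT / V_c) - 1),

    which reduces to the square-law pinch-off V_Dsat = V_GT as V_c -> inf.
    Returns 0 for a device that is off (V_GT <= 0).
    """
    if not v_c > 0:
        raise InvalidParameterError("v_c must be strictly positive")
    if v_gt <= 0:
        return 0.0
    return v_c * (math.sqrt(1.0 + 2.0 * v_gt / v_c) - 1.0)


def channel_current(v_gt: float, v_d, beta: float, v_c: float):
    """Clamped velocity-saturation channel current (A).

    Evaluates ``beta (2 V_GT V_D - V_D^2)/(1 + V_D/V_c)`` for V_D up to the
    saturation drain voltage and holds the peak value beyond it, which keeps
    the curve continuous and nondecreasing. Accepts scalar or array ``v_d``.
    This is the workhorse shared by the bare-device and biosensor currents
    and by the fitting objective (where beta and V_c are free parameters).
    """
    if not beta > 0:
        raise InvalidParameterError("beta must be strictly positive")
    if not v_c > 0:
        raise InvalidParameterError("v_c must be strictly positive")
    v_d_arr = np.asarray(v_d, dtype=float)
    if np.any(v_d_arr < 0):
        raise InvalidParameterError("drain voltage must be nonnegative")
    if v_gt <= 0:
        out = np.zeros_like(v_d_arr)
        return out if out.ndim else 0.0
    v_dsat = saturation_drain_voltage(v_gt, v_c)
    v_eff = np.minimum(v_d_arr, v_dsat)
    out = beta * (2.0 * v_gt * v_eff - v_eff * v_eff) / (1.0 + v_eff / v_c)
    return out if out.ndim else float(out)


def drain_current_bare(v_g: float, v_d, derived: DerivedParams, v_t: float):
    """Drain current of the bare transistor (no buffer, no analyte), in A.

    ``v_g`` is the applied gate voltage; the overdrive is V_GT = V_G - V_T.
    Scalar or array ``v_d`` (volts, nonnegative).
    """
    return channel_current(v_g - v_t, v_d, derived.beta, derived.critical_voltage)
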