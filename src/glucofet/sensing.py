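"""Solution-condition model: how buffer and glucose shift the gate voltage.

Glucose oxidase immobilised on the nanotube catalyses beta-D-glucose +
O2 -> D-glucono-delta-lactone + H2O2; hydrolysis of the lactone and
electro-oxidation of the peroxide release two protons and two electrons per
glucose molecule into the channel's environment. The extra carriers act like
an additional gate bias, so the sensor is modelled as the bare transistor
driven at an *effective* gate voltage

    V_GS,eff = V_GS(bare) + V_PBS + V_glucose(F_g).

``V_PBS`` is the shift from phosphate-buffered saline alone (a single
calibrated constant, 0.6 V at 1 mg/mL — no concentration law is invented
beyond that one calibration point) and ``V_glucose`` follows an empirical
piecewise-exponential dose-response law

    V_glucose(F_g) = 0                      if F_g = 0
                   = a - exp(-k F_g) [V]    if F_g > 0

with device-specific constants a = 1.42 V and k = 0.1 mM^-1 by default. Note
the law as written is *discontinuous* at F_g -> 0+ (it jumps to a - 1); that
jump is reproduced verbatim here, with a continuity-corrected alternative
``a (1 - exp(-k F_g))`` available behind the ``continuous`` flag. No redox
charge balance is computed — the stoichiometry above is mechanism rationale
only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .device import DerivedParams, channel_current
from .exceptions import InvalidParameterError, OutOfRangeError

__all__ = [
    "GlucoseResponseLaw",
    "SensingCondition",
    "glucose_gate_voltage",
    "inverse_glucose",
    "effective_gate_voltage",
    "drain_current_biosensor",
]


@dataclass(frozen=True)
class GlucoseResponseLaw:
    """Constants of the piecewise-exponential glucose/gate-voltage law.

    ``asymptote_voltage`` (a, volts) is the large-concentration plateau of
    the shift; ``rate_constant`` (k, per mM) sets how fast it is approached.
    Both are fit results for a particular sensor and are kept configurable
    so the law can be refit to other devices.
    """

    asymptote_voltage: float = 1.42
    rate_constant: float = 0.1

    def __post_init__(self) -> None:
        if not self.asymptote_voltage > 0:
            raise InvalidParameterError("asymptote_voltage must be strictly positive")
        if not self.rate_constant > 0:
            raise InvalidParameterError("rate_constant must be strictly positive")


@dataclass(frozen=True)
class SensingCondition:
    """One solution condition: buffer concentration/shift and glucose level.

    ``pbs_voltage`` must be 0 whenever ``pbs_concentration`` is 0 (no buffer,
    no buffer-induced shift).
    """

    pbs_concentration: float = 1.0  # mg/mL
    pbs_voltage: float = 0.6  # V
    glucose_concentration: float = 0.0  # mM
    law: GlucoseResponseLaw = field(default_factory=GlucoseResponseLaw)

    def __post_init__(self) -> None:
        if self.glucose_concentration < 0:
            raise InvalidParameterError("glucose_concentration must be nonnegative")
        if self.pbs_concentration < 0:
            raise InvalidParameterError("pbs_concentration must be nonnegative")
        if self.pbs_concentration == 0 and self.pbs_voltage != 0:
            raise InvalidParameterError("pbs_voltage must be 0 when pbs_concentration is 0")


def glucose_gate_voltage(f_g, law: GlucoseResponseLaw | None = None, *, continuous: bool = False):
    """Gate-voltage shift induced by glucose at concentration ``f_g`` (mM).

    Piecewise: exactly 0 at f_g = 0; ``a - exp(-k f_g)`` volts for f_g > 0
    (the printed, discontinuous form). With ``continuous=True`` the smoothed
    variant ``a (1 - exp(-k f_g))`` is used instead. Strictly increasing in
    f_g on (0, inf) with supremum a. Accepts scalar or array input.
    """
    law = law or GlucoseResponseLaw()
    f = np.asarray(f_g, dtype=np.longdouble)
    if np.any(f < 0):
        raise InvalidParameterError("glucose concentration must be nonnegative")
    # Extended precision: near the asymptote the subtraction a - exp(-k f)
    # cancels, and float64 rounding alone would spoil concentration
    # read-back beyond ~190 mM at the 1e-9 relative level.
    a = np.longdouble(law.asymptote_voltage)
    k = np.longdouble(law.rate_constant)
    if continuous:
        shift = a * (-np.expm1(-k * f))
    else:
        shift = np.where(f > 0, a - np.exp(-k * f), np.longdouble(0.0))
    return shift if shift.ndim else shift[()]


def inverse_glucose(v_glucose: float, law: GlucoseResponseLaw | None = None) -> float:
    """Concentration read-back: invert the glucose law analytically (mM).

    Defined for 0 (maps to 0 mM) and for the open range (a-1, a) attained by
    f_g > 0; values at or above the asymptote, or at or below a-1, have no
    preimage and raise :class:`OutOfRangeError`.
    """
    law = law or GlucoseResponseLaw()
    a = np.longdouble(law.asymptote_voltage)
    k = np.longdouble(law.rate_constant)
    if v_glucose == 0.0:
        return 0.0
    v = np.longdouble(v_glucose)
    if v >= a:
        raise OutOfRangeError(
            f"v_glucose={v_glucose!r} is at or above the asymptote "
            f"{law.asymptote_voltage} V; no finite concentration"
        )
    if v <= a - 1.0:
        raise OutOfRangeError(
            f"v_glucose={v_glucose!r} is at or below {float(a - 1.0)} V, "
            "outside the law's range for f_g > 0"
        )
    return float(-np.log(a - v) / k)


def effective_gate_voltage(v_gs_bare: float, condition: SensingCondition) -> float:
    """Effective gate voltage V_GS(bare) + V_PBS + V_glucose(F_g), in volts.

    Returned in float64: the glucose shift is downcast before the sum so
    that with all shifts zero the result (and hence the biosensor current)
    is bit-identical to the bare-device path.
    """
    shift = float(glucose_gate_voltage(condition.glucose_concentration, condition.law))
    return v_gs_bare + condition.pbs_voltage + shift


def drain_current_biosensor(
    v_gs_bare: float,
    v_d,
    condition: SensingCondition,
    derived: DerivedParams,
    v_t: float,
):
    """Biosensor drain current (A): the bare law at the effective gate voltage.

    With no buffer and no glucose this is bit-identical to the bare-device
    current; at fixed bias it increases strictly with glucose concentration
    while the device is on and below saturation.
    """
    v_eff = effective_gate_voltage(v_gs_bare, condition)
    return channel_current(v_eff - v_t, v_d, derived.beta, derived.critical_voltage)
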