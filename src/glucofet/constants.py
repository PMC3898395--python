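"""Physical constants used throughout the device model.

CODATA values are taken from :mod:`scipy.constants` and are deliberately not
user-configurable: the only material constant a user may vary is the relative
permittivity carried by the device geometry.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import constants as _sc


@dataclass(frozen=True)
class PhysicalConstants:
    """Fixed CODATA constants (SI units)."""

    elementary_charge: float = _sc.elementary_charge  # C
    planck_constant: float = _sc.Planck  # J s
    vacuum_permittivity: float = _sc.epsilon_0  # F/m

    def __post_init__(self) -> None:
        for name in ("elementary_charge", "planck_constant", "vacuum_permittivity"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


#: Module-level singleton; import this instead of instantiating.
CONSTANTS = PhysicalConstants()

# Unit-conversion helpers (kept explicit so scales never drift silently).
FARAD_PER_METER_TO_ATTOFARAD_PER_MICRON = 1e12  # 1 F/m == 1e12 aF/um
AMPERE_TO_MICROAMPERE = 1e6
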