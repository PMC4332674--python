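"""Physical constants and unit conversions used throughout the package.

All voltages are millivolts, all rates per second, energies joules,
tensions mN/m and protein area changes nm² unless noted otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

FARADAY = 96485.33212  # C/mol
GAS_CONSTANT = 8.31446261815324  # J/(mol K)
BOLTZMANN = 1.380649e-23  # J/K

#: 1 mmHg in pascal
MMHG_TO_PA = 133.322
#: (1 mN/m) x (1 nm^2) in joule
MN_PER_M_NM2_TO_J = 1e-21


@dataclass(frozen=True)
class PhysicalConstants:
    """Temperature-dependent constants for rate and tension calculations.

    The default temperature (~293 K) gives the thermal voltage RT/F = 25.3 mV,
    a conventional room-temperature value for oocyte patch recordings.
    """

    temperature: float = field(default=25.3e-3 * FARADAY / GAS_CONSTANT)  # K

    @classmethod
    def from_thermal_voltage(cls, rtf_mv: float) -> "PhysicalConstants":
        """Build constants whose RT/F equals ``rtf_mv`` millivolts."""
        if rtf_mv <= 0:
            raise ValueError("thermal voltage must be positive")
        return cls(temperature=rtf_mv * 1e-3 * FARADAY / GAS_CONSTANT)

    @property
    def thermal_voltage(self) -> float:
        """RT/F in millivolts."""
        return GAS_CONSTANT * self.temperature / FARADAY * 1e3

    @property
    def kt(self) -> float:
        """kB*T in joules."""
        return BOLTZMANN * self.temperature


DEFAULT_CONSTANTS = PhysicalConstants()
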