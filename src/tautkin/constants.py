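"""Physical constants and unit conversions shared by all rate and energy formulas.

Every formula in the package takes an explicit :class:`ConstantsConvention`
so that the numerical convention (constant values, calorie definition) is a
single injectable object rather than scattered literals.  The default is
CODATA 2018 (exact SI values for k_B, h, c) with the thermochemical calorie
(4.184 J).
"""

from __future__ import annotations

from dataclasses import dataclass

#: kcal·mol⁻¹ per hartree, used by the EML potential-energy-density formula.
HARTREE_TO_KCAL_PER_MOL = 627.5095


@dataclass(frozen=True)
class ConstantsConvention:
    """Bundle of physical constants defining the unit convention.

    Attributes
    ----------
    boltzmann : float
        Boltzmann constant k_B, J·K⁻¹.
    planck : float
        Planck constant h, J·s.
    gas_constant : float
        Molar gas constant R, J·mol⁻¹·K⁻¹.
    light_speed : float
        Speed of light, cm·s⁻¹ (wavenumber convention).
    cal_to_joule : float
        Joules per thermochemical calorie.
    """

    boltzmann: float = 1.380649e-23
    planck: float = 6.62607015e-34
    gas_constant: float = 8.31446261815324
    light_speed: float = 2.99792458e10
    cal_to_joule: float = 4.184

    def __post_init__(self) -> None:
        for name in ("boltzmann", "planck", "gas_constant", "light_speed", "cal_to_joule"):
            if getattr(self, name) <= 0:
                raise ValueError(f"constant {name!r} must be strictly positive")

    def kBT_over_h(self, temperature: float) -> float:
        """Eyring prefactor k_B·T/h in s⁻¹ (≈6.21e12 at 298.15 K)."""
        _require_positive_temperature(temperature)
        return self.boltzmann * temperature / self.planck

    def kBT_in_wavenumbers(self, temperature: float) -> float:
        """Thermal energy expressed as a wavenumber, k_B·T/(h·c) in cm⁻¹."""
        _require_positive_temperature(temperature)
        return self.boltzmann * temperature / (self.planck * self.light_speed)

    def RT_kcal(self, temperature: float) -> float:
        """R·T in kcal·mol⁻¹ (≈0.5925 at 298.15 K)."""
        _require_positive_temperature(temperature)
        return self.gas_constant * temperature / (self.cal_to_joule * 1000.0)


def _require_positive_temperature(temperature: float) -> None:
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")


#: Default convention used throughout the package.
CODATA2018 = ConstantsConvention()

#: Standard temperature ("normal conditions"), K.
STANDARD_TEMPERATURE = 298.15
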