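"""Physical constants and unit conversions.

The package works in a fixed unit system throughout:

================  ==========================
length            angstrom (Å)
time              nanosecond (ns)
energy            kcal/mol
charge            elementary charge (e)
voltage           millivolt (mV)
temperature       kelvin (K)
diffusivity       Å²/ns
flux              crossing events / ns
electric current  picoampere (pA)
================  ==========================

All conversions are defined in this one module so that the numerical
values are stated exactly once.
"""

from __future__ import annotations

#: Boltzmann constant, kcal/(mol K).
KB_KCAL_MOL_K: float = 0.0019872041

#: Energy of one elementary charge across 1 mV, kcal/mol (i.e. 1 e*mV).
#: 23.0605 kcal/mol per e*V.
KCAL_MOL_PER_E_MV: float = 0.0230605

#: Electric current carried by one elementary charge per nanosecond, pA.
#: 1 e/ns = 1.602176634e-19 C / 1e-9 s = 0.1602 nA = 160.2 pA.
PA_PER_E_PER_NS: float = 160.2176634

#: Default temperature (K): room-temperature electrophysiology convention.
DEFAULT_TEMPERATURE: float = 298.15


def beta(temperature: float) -> float:
    """Inverse thermal energy 1/(kB T) in mol/kcal."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return 1.0 / (KB_KCAL_MOL_K * temperature)


def thermal_voltage_mv(temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Thermal voltage kB*T/e in mV (RT/F; 25.693 mV at 298.15 K)."""
    return KB_KCAL_MOL_K * temperature / KCAL_MOL_PER_E_MV
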