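"""Unit system and physical constants.

Working units used everywhere in this package: length in Å, time in ns,
viscosity in cP, temperature in K, pressure in bar.  The derived working
energy unit is cP·Å³/ns (= 1e-24 J), chosen so that Stokes–Einstein style
expressions ``k_B*T / (6*pi*eta[cP]*R[Å])`` evaluate directly to Å²/ns
without any further conversion factors.

All conversion constants live here; no other module hard-codes units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Boltzmann constant in SI (J/K), CODATA exact value.
BOLTZMANN_SI = 1.380649e-23

#: Avogadro constant (1/mol), exact.
AVOGADRO = 6.02214076e23

#: Default temperature of the study conditions (K).
TEMPERATURE_DEFAULT = 298.0

#: Joule -> working energy unit (cP·Å³/ns).
#: 1 J = 1 Pa·s·m³/s = 1e3 cP · 1e30 Å³ / 1e9 ns = 1e24 cP·Å³/ns.
JOULE_TO_WORKING = 1e24

#: bar -> working pressure unit (cP/ns).  1 bar = 1e5 Pa = 1e5 Pa·s/s
#: = 1e8 cP/s = 0.1 cP/ns.
BAR_TO_WORKING = 0.1

#: number density 1/Å³ -> mM.  1/Å³ = 1e27/L; divide by N_A for mol/L,
#: multiply by 1e3 for mmol/L.
PER_A3_TO_MM = 1e30 / AVOGADRO


def thermal_energy(temperature: float = TEMPERATURE_DEFAULT) -> float:
    """k_B*T in working energy units (cP·Å³/ns).

    With this energy unit, ``thermal_energy(T)/(6*pi*eta*R)`` with eta in cP
    and R in Å is a diffusion coefficient in Å²/ns.

    Raises
    ------
    ValueError
        If ``temperature`` is not positive.
    """
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return BOLTZMANN_SI * temperature * JOULE_TO_WORKING


@dataclass(frozen=True)
class PhysicalConstants:
    """Bundle of constants plus SI <-> working-unit conversions.

    ``to_si``/``from_si`` round-trip any quantity to better than 1e-12
    relative (the factors are exact powers of ten).
    """

    boltzmann: float = BOLTZMANN_SI
    temperature_default: float = TEMPERATURE_DEFAULT
    #: multiply a working-unit value by this to get SI
    _to_si: dict = field(
        default_factory=lambda: {
            "length": 1e-10,        # Å -> m
            "time": 1e-9,           # ns -> s
            "viscosity": 1e-3,      # cP -> Pa·s
            "pressure": 1e5,        # bar -> Pa
            "energy": 1e-24,        # cP·Å³/ns -> J
            "diffusion": 1e-11,     # Å²/ns -> m²/s
        }
    )

    def to_si(self, value: float, quantity: str) -> float:
        return value * self._to_si[quantity]

    def from_si(self, value: float, quantity: str) -> float:
        return value / self._to_si[quantity]


def stokes_einstein_dt(eta_cp: float, radius_A: float,
                       temperature: float = TEMPERATURE_DEFAULT) -> float:
    """Translational Stokes–Einstein diffusion D = k_BT/(6·pi·eta·R), Å²/ns."""
    if eta_cp <= 0 or radius_A <= 0:
        raise ValueError("viscosity and radius must be positive")
    return thermal_energy(temperature) / (6.0 * np.pi * eta_cp * radius_A)


def stokes_einstein_dr(eta_cp: float, radius_A: float,
                       temperature: float = TEMPERATURE_DEFAULT) -> float:
    """Rotational Stokes–Einstein diffusion D_r = k_BT/(8·pi·eta·R³), 1/ns."""
    if eta_cp <= 0 or radius_A <= 0:
        raise ValueError("viscosity and radius must be positive")
    return thermal_energy(temperature) / (8.0 * np.pi * eta_cp * radius_A ** 3)
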