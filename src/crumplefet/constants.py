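"""Physical constants and unit conversions shared by all stages.

All CODATA values come from :mod:`scipy.constants`.  Internal unit
conventions across the package: distances in nm, concentrations in
mol L⁻¹ (molar), potentials in V, Dirac shifts in mV, surface charge
densities in C m⁻², areas in m².
"""

from __future__ import annotations

from dataclasses import dataclass

import scipy.constants as _sc


@dataclass(frozen=True)
class Constants:
    """CODATA physical constants used by the electrostatics chain."""

    faraday_F: float = _sc.physical_constants["Faraday constant"][0]  # C mol^-1
    elementary_charge_e: float = _sc.elementary_charge  # C
    vacuum_permittivity_eps0: float = _sc.epsilon_0  # F m^-1
    avogadro_NA: float = _sc.Avogadro  # mol^-1
    boltzmann_kB: float = _sc.Boltzmann  # J K^-1

    def __post_init__(self) -> None:
        for name, value in vars(self).items():
            if not value > 0:
                raise ValueError(f"constant {name} must be strictly positive")


CONSTANTS = Constants()

# unit conversion factors
NM_TO_M = 1e-9
M_TO_NM = 1e9
NM3_TO_L = 1e-24  # 1 nm^3 in litres
MOLAR_TO_SI = 1e3  # mol L^-1 -> mol m^-3
V_TO_MV = 1e3
MV_TO_V = 1e-3
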