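"""Ionic screening analysis of the electric double layer.

Implements the screening-factor statistic

    SF(z) = ∫₀ᶻ F ([Na⁺] − [Cl⁻]) dz' / |σ|,

the screening-onset location, the unscreened adsorbed-DNA charge, the
doubly integrated electrostatic potential profile, the Debye length and a
capacitance proxy.  SF is dimensionless: concentrations enter in SI
(mol m⁻³), distances in metres, F in C mol⁻¹ and σ in C m⁻².
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .constants import CONSTANTS, MOLAR_TO_SI, NM_TO_M
from .datatypes import (ConcentrationProfile, DebyeParams, PotentialProfile,
                        ScreeningResult)


class GridError(ValueError):
    """Profiles do not share a bin grid."""


def debye_length(ionic_strength: float, temperature: float = 298.15,
                 relative_permittivity: float = 78.5) -> DebyeParams:
    """Debye screening length of a symmetric 1:1 electrolyte.

    λ_D = sqrt(ε₀ ε_r k_B T / (2 N_A e² I·10³)) with the ionic strength I
    in mol L⁻¹; the result is returned in nm.  At physiological ionic
    strength (150 mM, 298 K, ε_r 78.5) this is ≈0.78 nm, below 1 nm.
    """
    if ionic_strength <= 0 or temperature <= 0 or relative_permittivity <= 0:
        raise ValueError("ionic strength, temperature and permittivity must be > 0")
    c = CONSTANTS
    num = (c.vacuum_permittivity_eps0 * relative_permittivity
           * c.boltzmann_kB * temperature)
    den = 2.0 * c.avogadro_NA * c.elementary_charge_e**2 * ionic_strength * 1e3
    lam_m = np.sqrt(num / den)
    return DebyeParams(ionic_strength, temperature, relative_permittivity,
                       lam_m / NM_TO_M)


def surface_potential_linear(sigma: float, debye: DebyeParams) -> float:
    """Linearised Grahame relation ψ₀ = σ λ_D / (ε₀ ε_r), volts."""
    lam_m = debye.debye_length * NM_TO_M
    return sigma * lam_m / (CONSTANTS.vacuum_permittivity_eps0
                            * debye.relative_permittivity)


def screening_factor(na_profile: ConcentrationProfile,
                     cl_profile: ConcentrationProfile,
                     sigma: float) -> ScreeningResult:
    """Cumulative net ionic charge between the surface and z, over |σ|.

    The binned concentrations are piecewise constant, so the integral is
    evaluated exactly per bin (midpoint/rectangle rule); the returned SF
    lives on the bin-edge grid with SF(0) = 0.  The raw statistic is not
    clamped and may exceed 1.
    """
    if sigma == 0:
        raise ValueError("sigma = 0: screening factor normalisation undefined")
    if not na_profile.same_grid(cl_profile):
        raise GridError("Na+ and Cl- profiles must share a bin grid")
    net_si = (na_profile.concentration - cl_profile.concentration) * MOLAR_TO_SI
    widths_m = na_profile.widths * NM_TO_M
    increments = CONSTANTS.faraday_F * net_si * widths_m / abs(sigma)
    sf = np.concatenate([[0.0], np.cumsum(increments)])
    d_grid = na_profile.bin_edges.copy()
    if d_grid[0] != 0.0:
        # profiles binned away from the surface: anchor the curve at d = 0
        d_grid = np.concatenate([[0.0], d_grid])
        sf = np.concatenate([[0.0], sf])
    return ScreeningResult(d_grid=d_grid, sf=sf, sigma=sigma)


def screening_onset(result: ScreeningResult, threshold: float = 0.05) -> Optional[float]:
    """Smallest distance where SF first reaches ``threshold`` (nm).

    Linear interpolation between grid points; None when SF never reaches
    the threshold (flagged by the caller).
    """
    sf, d = result.sf, result.d_grid
    above = np.nonzero(sf >= threshold)[0]
    if above.size == 0:
        return None
    i = above[0]
    if i == 0:
        return float(d[0])
    frac = (threshold - sf[i - 1]) / (sf[i] - sf[i - 1])
    return float(d[i - 1] + frac * (d[i] - d[i - 1]))


def unscreened_dna_charge(dna_profile: ConcentrationProfile,
                          result: ScreeningResult,
                          area_A: Optional[float] = None) -> float:
    """Adsorbed DNA charge not neutralised by intervening counter-ions.

    N_unscreened = ∫ ρ_DNA(z) (1 − min(SF(z), 1)) dz, in elementary
    charges per m² of device area (the DNA profile is per-volume, one −e
    site per entry).  SF is clamped to [0, 1] only inside this weighting.
    The result is clamped to [0, total adsorbed DNA charge].
    """
    edges = dna_profile.bin_edges
    sf_at_edges = np.interp(edges, result.d_grid, result.sf)
    sf_mid = 0.5 * (sf_at_edges[:-1] + sf_at_edges[1:])
    weight = 1.0 - np.clip(sf_mid, 0.0, 1.0)
    per_bin = (dna_profile.concentration * MOLAR_TO_SI * CONSTANTS.avogadro_NA
               * dna_profile.widths * NM_TO_M)  # sites per m^2 per bin
    total = float(per_bin.sum())
    n_unscr = float(np.clip((per_bin * weight).sum(), 0.0, total))
    if area_A is not None:
        result.n_dna_unscreened = n_unscr
    return n_unscr


def potential_profile(q_per_bin: np.ndarray, grid: np.ndarray, area_A: float,
                      z0: Optional[float] = None,
                      relative_permittivity: float = 1.0) -> PotentialProfile:
    """Electrostatic potential V(z) = −∬_{z0}^{z} q(z')/(A ε₀) dz' dz'.

    Parameters
    ----------
    q_per_bin : array
        Net charge (C) per bin — ions, DNA and surface charge together.
    grid : array
        Uniform bin-edge grid in nm (len(q) + 1 entries).
    area_A : float
        Device/trench footprint area in m².
    z0 : float, optional
        Reference where both V and dV/dz vanish; defaults to the grid
        start (the surface side).
    relative_permittivity : float
        1.0 for explicit-solvent charge profiles (solvent polarisation is
        part of q); set to the solvent ε_r for implicit-solvent profiles.

    The double integral is evaluated by two cumulative trapezoids on the
    bin-centre grid.
    """
    grid = np.asarray(grid, dtype=float)
    q = np.asarray(q_per_bin, dtype=float)
    if grid.size != q.size + 1:
        raise ValueError("grid must have len(q_per_bin) + 1 edges")
    widths = np.diff(grid)
    if not np.allclose(widths, widths[0], rtol=1e-6):
        raise ValueError("potential integration requires a uniform grid")
    if not area_A > 0:
        raise ValueError("area_A must be > 0")
    centers_nm = 0.5 * (grid[:-1] + grid[1:])
    z_m = centers_nm * NM_TO_M
    rho_line = q / (widths[0] * NM_TO_M)  # C per metre of z
    eps = CONSTANTS.vacuum_permittivity_eps0 * relative_permittivity

    from scipy.integrate import cumulative_trapezoid

    e_field = cumulative_trapezoid(rho_line / (area_A * eps), z_m, initial=0.0)
    z0 = centers_nm[0] if z0 is None else float(z0)
    e0 = np.interp(z0 * NM_TO_M, z_m, e_field)
    v_full = -cumulative_trapezoid(e_field - e0, z_m, initial=0.0)
    v = v_full - np.interp(z0 * NM_TO_M, z_m, v_full)
    return PotentialProfile(d_grid=centers_nm, v=v, reference_z0=z0, area_A=area_A)


def capacitance_from_profile(potential: PotentialProfile, sigma: float,
                             surface_z: Optional[float] = None,
                             plateau_fraction: float = 0.1,
                             plateau_rtol: float = 0.02) -> float:
    """Effective double-layer capacitance C = |σ| / |V(surface) − V(bulk)|.

    The bulk potential is the mean of the last ``plateau_fraction`` of the
    grid.  When the potential is still drifting there (relative drift above
    ``plateau_rtol`` of the total potential drop) the profile is flagged
    via ``potential.plateau_ok`` and the estimate returned anyway.
    """
    z, v = potential.d_grid, potential.v
    n_tail = max(int(round(plateau_fraction * z.size)), 2)
    plateau = float(np.mean(v[-n_tail:]))
    v_surf = float(np.interp(surface_z, z, v)) if surface_z is not None else float(v[0])
    drop = abs(v_surf - plateau)
    if drop == 0.0:
        raise ValueError("zero potential drop: capacitance undefined")
    drift = abs(v[-1] - v[-n_tail])
    potential.plateau_ok = bool(drift <= plateau_rtol * drop)
    return abs(sigma) / drop
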