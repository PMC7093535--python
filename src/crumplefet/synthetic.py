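"""Synthetic generators for every input of the analysis chain.

Ion configurations follow linearised Gouy–Chapman (Debye–Hückel)
statistics: the mean-field potential ψ(d) = ψ₀ e^(−d/λ_D) decays with the
Debye length in the distance-from-surface coordinate d, ions are placed
by rejection sampling with Boltzmann weights exp(∓eψ/kT), and a hard-core
exclusion radius keeps ions off the surface manifold.  Screened-Coulomb
terms couple the ions to the DNA backbone charges, and a concave
confinement penalty reproduces the exclusion of hydrated ions from
narrow valleys that makes crumpled sensing surfaces special (see the
methods note).  Transfer curves are ambipolar
V-shapes with a controllable Dirac point; dose–response tables follow a
Sips isotherm with Gaussian noise and negative-control replicates.
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .constants import CONSTANTS, NM3_TO_L, NM_TO_M
from .datatypes import (DEFAULT_CHARGES, DnaPlacement, DoseResponse,
                        IonBathSpec, ParticleFrame, SipsParams, TransferCurve)
from .screening import debye_length, surface_potential_linear
from .surfaces import SurfaceModel, surface_distance, surface_geometry

DEFAULT_BOX = (12.5, 12.5, 5.0)  # nm, footprint of the flat reference system
ION_EXCLUSION_RADIUS = 0.15  # nm hard-core stand-off from the surface


class CapacityError(RuntimeError):
    """Box cannot hold the requested number of ions."""


def sips_shift(concentration, dv_max: float, affinity_K: float,
               heterogeneity_a: float):
    """Noiseless Sips (Langmuir–Freundlich) isotherm, mV.

    |ΔV|(C) = ΔV_max (K C)^a / (1 + (K C)^a)
    """
    kc = np.power(np.asarray(concentration, dtype=float) * affinity_K,
                  heterogeneity_a)
    return dv_max * kc / (1.0 + kc)


# --- DNA track ------------------------------------------------------------

def dna_charge_sites(dna: DnaPlacement, surface: SurfaceModel,
                     box: Sequence[float]) -> np.ndarray:
    """Backbone charge-site coordinates (nm) along the chosen geometry.

    One site per base per ``charges_per_base`` at a fixed rise, following
    the surface at the stand-off distance.  Tracks longer than the box
    wrap periodically (the simulated systems are periodic in x and y).
    """
    lx, ly = float(box[0]), float(box[1])
    n = dna.n_sites
    t = (np.arange(n) - (n - 1) / 2.0) * dna.rise_per_base
    geometry, wl, amp = dna.geometry, surface.wavelength, surface.amplitude

    if geometry == "flat":
        if surface.kind != "flat":
            raise ValueError("geometry 'flat' requires a flat surface")
        x = (lx / 2.0 + t) % lx
        return np.column_stack([x, np.full(n, ly / 2.0), np.full(n, dna.standoff)])

    if geometry in ("concave", "convex"):
        if surface.kind != "sinusoid":
            raise ValueError(f"geometry {geometry!r} requires a sinusoidal surface")
        if geometry == "concave":
            # valley line nearest the box centre (cos minimum)
            x0 = wl * (np.round(lx / 2.0 / wl - 0.5) + 0.5)
            z = -amp + dna.standoff
        else:
            x0 = wl * np.round(lx / 2.0 / wl)
            z = amp + dna.standoff
        y = (ly / 2.0 + t) % ly
        return np.column_stack([np.full(n, x0), y, np.full(n, z)])

    if geometry == "across":
        if surface.kind != "sinusoid":
            raise ValueError("geometry 'across' requires a sinusoidal surface")
        x = (lx / 2.0 + t) % lx
        k = 2.0 * np.pi / wl
        slope = -amp * k * np.sin(k * x)
        norm = np.sqrt(1.0 + slope**2)
        px = x - dna.standoff * slope / norm
        pz = surface.height(x) + dna.standoff / norm
        return np.column_stack([px % lx, np.full(n, ly / 2.0), pz])

    if geometry == "trench_bottom":
        if surface.kind != "trench":
            raise ValueError("geometry 'trench_bottom' requires a trench surface")
        y = (ly / 2.0 + t) % ly
        z = -surface.trench_radius + dna.standoff
        return np.column_stack([np.full(n, surface.trench_x0), y, np.full(n, z)])

    raise ValueError(f"unknown geometry {geometry!r}")


# --- ion configurations ---------------------------------------------------

DNA_CONTACT_RADIUS = 0.3  # nm closest ion approach to a backbone site
CONFINEMENT_RANGE = 0.7  # nm, hydrated-ion diameter scale of the confinement penalty
CONFINEMENT_PENALTY_KT = 5.0  # strength of the concave confinement (dehydration) penalty


def generate_ion_configuration(surface: SurfaceModel, bath: IonBathSpec,
                               n_ions_target: Optional[int] = None,
                               dna: Optional[DnaPlacement] = None,
                               box: Sequence[float] = DEFAULT_BOX,
                               ion_radius: float = ION_EXCLUSION_RADIUS,
                               dna_contact: float = DNA_CONTACT_RADIUS,
                               confinement_penalty_kT: float = CONFINEMENT_PENALTY_KT,
                               confinement_range: float = CONFINEMENT_RANGE,
                               seed: Optional[int] = None,
                               batch: int = 100_000,
                               max_batches: int = 50) -> ParticleFrame:
    """Sample an electroneutral Na⁺/Cl⁻ (+ DNA) configuration.

    Ions are rejection-sampled from Boltzmann weights of the linearised
    mean-field potential: the Debye–Hückel surface term ψ₀ e^(−d/λ_D) in
    the distance coordinate plus a screened-Coulomb term from each DNA
    backbone site, evaluated no closer than the steric contact distance.
    Ions are excluded within ``ion_radius`` of the surface manifold and
    within ``dna_contact`` of any DNA site — in confined concave regions
    these exclusions push the DNA's counter-ion cloud away from the
    surface, which is the geometric origin of reduced screening there.
    Near concave surface regions a charge-independent confinement
    (dehydration) penalty u = confinement_penalty_kT · kT · κ⁺ ·
    confinement_range · exp(−d/confinement_range) suppresses occupancy
    (κ⁺ is the local concave curvature, the range is a hydrated-ion
    diameter): hydrated ions cannot pack into concave valleys, so the
    counter-ion cloud there is displaced away from the surface and the
    double layer of a crumpled surface is more diffuse than a flat
    one's.  Flat surfaces (κ⁺ = 0) are unaffected.  Ion counts default to the bulk-density expectation over
    the accessible volume; the Na⁺/Cl⁻ split is then adjusted so that
    total ion charge + DNA charge + σ·A is zero to within one elementary
    charge.
    """
    rng = np.random.default_rng(bath.seed if seed is None else seed)
    lx, ly, lz = (float(v) for v in box)
    z_lo = surface.z_min()
    if lz <= max(ion_radius * 4.0, -z_lo):
        raise CapacityError("box height too small for an ion atmosphere")

    debye = debye_length(bath.bulk_concentration, bath.temperature,
                         bath.relative_permittivity)
    lam = debye.debye_length  # nm
    psi0 = surface_potential_linear(surface.sigma, debye)
    kT = CONSTANTS.boltzmann_kB * bath.temperature
    beta_e = CONSTANTS.elementary_charge_e / kT

    area = surface.wetted_area(lx, ly)
    if surface.area_A is None:
        surface.area_A = area

    dna_sites = (dna_charge_sites(dna, surface, box) if dna is not None
                 else np.empty((0, 3)))
    n_dna = dna_sites.shape[0]
    site_charge = -1.0  # e per backbone site
    # screened-Coulomb prefactor e/(4π ε₀ ε_r), V·m
    coul = (CONSTANTS.elementary_charge_e
            / (4.0 * np.pi * CONSTANTS.vacuum_permittivity_eps0
               * bath.relative_permittivity))

    def dna_potential(pts: np.ndarray) -> np.ndarray:
        """Σ over sites of the screened site potential, volts (can be 0-size)."""
        if n_dna == 0:
            return np.zeros(pts.shape[0])
        diff = pts[:, None, :] - dna_sites[None, :, :]
        diff[:, :, 0] -= lx * np.round(diff[:, :, 0] / lx)  # periodic x, y
        diff[:, :, 1] -= ly * np.round(diff[:, :, 1] / ly)
        r = np.sqrt((diff**2).sum(axis=2)) * NM_TO_M
        r_eff = np.maximum(r, dna_contact * NM_TO_M)
        psi = site_charge * coul * np.exp(-r_eff / (lam * NM_TO_M)) / r_eff
        too_close = (r < dna_contact * NM_TO_M).any(axis=1)
        out = psi.sum(axis=1)
        out[too_close] = np.nan  # steric overlap marker
        return out

    def weight(q: float, d: np.ndarray, kappa: np.ndarray,
               psi_dna: np.ndarray) -> np.ndarray:
        u_conf = (confinement_penalty_kT * kappa * confinement_range
                  * np.exp(-np.maximum(d, 0.0) / confinement_range))
        w = np.exp(-q * beta_e * (psi0 * np.exp(-d / lam) + psi_dna) - u_conf)
        return np.where(np.isnan(psi_dna), 0.0, w)

    # proposal cloud for expectations and rejection sampling
    v_prop = lx * ly * (lz - z_lo)  # nm^3 (z in [z_lo, lz])

    def propose(m: int):
        pts = np.column_stack([rng.uniform(0, lx, m), rng.uniform(0, ly, m),
                               rng.uniform(z_lo, lz, m)])
        if surface.kind == "flat":
            d, kappa = pts[:, 2], np.zeros(m)
        else:
            d, kappa = surface_geometry(pts, surface)
        ok = d >= ion_radius
        return pts, d, kappa, ok, dna_potential(pts)

    pts0, d0, kap0, ok0, psi_d0 = propose(batch)
    w_na = np.where(ok0, weight(+1.0, d0, kap0, psi_d0), 0.0)
    w_cl = np.where(ok0, weight(-1.0, d0, kap0, psi_d0), 0.0)
    per_species_bulk = bath.bulk_concentration * CONSTANTS.avogadro_NA * v_prop * NM3_TO_L
    n_na_exp = per_species_bulk * float(np.mean(w_na))
    n_cl_exp = per_species_bulk * float(np.mean(w_cl))

    delta_req = int(round(n_dna - surface.sigma * area
                          / CONSTANTS.elementary_charge_e))
    if n_ions_target is not None:
        n_cl = max((int(n_ions_target) - delta_req) // 2, 0)
    else:
        n_cl = max(int(round(n_cl_exp)), 0)
    n_na = n_cl + delta_req
    if n_na < 0:
        raise ValueError("electroneutrality requires negative Na+ count; "
                         "increase box or ion target")

    # rejection bound: surface term at contact plus the site potential of
    # one touching site and its chain neighbours
    psi_dna_max = 0.0
    if n_dna:
        rise_m = (dna.rise_per_base if dna is not None else 0.7) * NM_TO_M
        r_chain = np.maximum(np.arange(n_dna) * rise_m, dna_contact * NM_TO_M)
        psi_dna_max = float(np.sum(
            2.0 * coul * np.exp(-r_chain / (lam * NM_TO_M)) / r_chain))
    w_bound = np.exp(beta_e * (abs(psi0) + psi_dna_max))

    def sample(q: float, n_needed: int) -> np.ndarray:
        out = []
        got = 0
        pts, d, kap, ok, psi_d = pts0, d0, kap0, ok0, psi_d0
        for _ in range(max_batches):
            w = np.where(ok, weight(q, d, kap, psi_d), 0.0)
            keep = rng.random(w.size) < w / w_bound
            sel = pts[keep]
            out.append(sel)
            got += sel.shape[0]
            if got >= n_needed:
                break
            pts, d, kap, ok, psi_d = propose(batch)
        else:
            raise CapacityError(f"could not place {n_needed} ions after "
                                f"{max_batches} batches")
        if got < n_needed:
            raise CapacityError(f"could not place {n_needed} ions")
        return np.concatenate(out, axis=0)[:n_needed]

    na_pos = sample(+1.0, n_na)
    cl_pos = sample(-1.0, n_cl)

    positions = np.concatenate([dna_sites, na_pos, cl_pos], axis=0)
    species = np.array(["DNA_charge"] * n_dna + ["Na+"] * n_na + ["Cl-"] * n_cl,
                       dtype=object)
    return ParticleFrame(positions=positions, species=species,
                         charge_per_species=dict(DEFAULT_CHARGES),
                         box=np.array([lx, ly, lz]), surface=surface)


# --- transfer curves ------------------------------------------------------

DEFAULT_IV_PARAMS = {
    "v_min": -0.5, "v_max": 1.0, "n_points": 301,  # the measured sweep window
    "i_min": 1e-6, "k_h": 2e-5, "k_e": 2e-5, "p": 1.0,
}


def generate_transfer_curve(dirac_v: float, params: Optional[Mapping] = None,
                            noise_sd: float = 0.0, seed: int = 0,
                            label: str = "") -> TransferCurve:
    """Ambipolar V-shaped transfer curve with its minimum at ``dirac_v``.

    I(V) = I_min + k_h max(V_D − V, 0)^p + k_e max(V − V_D, 0)^p plus
    Gaussian current noise.  With zero noise the on-grid argmin is the
    grid point nearest V_D.
    """
    p = dict(DEFAULT_IV_PARAMS)
    p.update(params or {})
    if p["k_h"] <= 0 or p["k_e"] <= 0:
        raise ValueError("branch slopes k_h and k_e must be positive")
    v = np.linspace(p["v_min"], p["v_max"], int(p["n_points"]))
    i = (p["i_min"]
         + p["k_h"] * np.maximum(dirac_v - v, 0.0) ** p["p"]
         + p["k_e"] * np.maximum(v - dirac_v, 0.0) ** p["p"])
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        i = i + rng.normal(0.0, noise_sd, i.size)
    i = np.maximum(i, 1e-3 * p["i_min"])  # keep currents physical
    return TransferCurve(v_gs=v, i_ds=i, label=label)


# --- dose-response tables -------------------------------------------------

def generate_dose_response(sips: SipsParams,
                           concentrations: Sequence[float]) -> DoseResponse:
    """Sips-shaped |Dirac shift| table with negative-control replicates.

    Each positive concentration gets ``n_replicates`` noisy readings of
    the isotherm; ``n_replicates`` zero-concentration negative controls
    carry noise only.  Fully reproducible under a fixed seed.
    """
    conc = np.asarray(concentrations, dtype=float)
    if (conc <= 0).any():
        raise ValueError("concentrations must be positive; negative controls "
                         "are generated automatically at concentration 0")
    rng = np.random.default_rng(sips.seed)
    rows = []
    for c in conc:
        mu = float(sips_shift(c, sips.dv_max, sips.affinity_K, sips.heterogeneity_a))
        for rep in range(sips.n_replicates):
            noise = rng.normal(0.0, sips.noise_sd) if sips.noise_sd > 0 else 0.0
            rows.append((c, mu + noise, rep, False))
    for rep in range(sips.n_replicates):
        noise = rng.normal(0.0, sips.noise_sd) if sips.noise_sd > 0 else 0.0
        rows.append((0.0, noise, rep, True))
    table = pd.DataFrame(rows, columns=["concentration", "shift_mV",
                                        "replicate_id", "is_negative_control"])
    return DoseResponse(table)
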