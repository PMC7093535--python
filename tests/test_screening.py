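"""Screening factor, onset, unscreened charge, potential, Debye length
and the capacitance proxy against closed-form electrostatics."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import crumplefet as cf
from crumplefet.constants import CONSTANTS, MOLAR_TO_SI, NM_TO_M
from crumplefet.datatypes import ConcentrationProfile
from crumplefet.screening import GridError


def _profile(edges, conc, species="Na+"):
    edges = np.asarray(edges, float)
    return ConcentrationProfile(edges, species, np.asarray(conc, float),
                                np.ones(edges.size - 1))


def _gc_profiles(lam, sigma, c_bulk=0.6, d_max=8.0, width=0.002):
    """Linearised Gouy–Chapman net-charge split into Na+/Cl- profiles."""
    edges = np.arange(0.0, d_max + width / 2, width)
    cen = 0.5 * (edges[:-1] + edges[1:])
    net_molar = ((-sigma / (lam * NM_TO_M)) * np.exp(-cen / lam)
                 / CONSTANTS.faraday_F / MOLAR_TO_SI)
    na = _profile(edges, c_bulk + net_molar / 2)
    cl = _profile(edges, c_bulk - net_molar / 2, "Cl-")
    return na, cl


# --- screening factor -----------------------------------------------------

def test_equal_profiles_give_zero_sf():
    edges = np.arange(0, 5.01, 0.1)
    na = _profile(edges, np.full(50, 0.6))
    cl = _profile(edges, np.full(50, 0.6), "Cl-")
    res = cf.screening_factor(na, cl, -0.02)
    assert np.all(res.sf == 0.0)


def test_step_profile_integrates_to_unity():
    """Net charge c0 on [0, L], zero beyond, with |sigma| = F·c0·L."""
    c0, L = 0.05, 1.0
    edges = np.arange(0.0, 3.001, 0.05)
    cen = 0.5 * (edges[:-1] + edges[1:])
    net = np.where(cen < L, c0, 0.0)
    na = _profile(edges, 0.6 + net)
    cl = _profile(edges, np.full(cen.size, 0.6), "Cl-")
    sigma = CONSTANTS.faraday_F * c0 * MOLAR_TO_SI * L * NM_TO_M
    res = cf.screening_factor(na, cl, sigma)
    sf_at = np.interp([L, 2.0, 3.0], res.d_grid, res.sf)
    np.testing.assert_allclose(sf_at, 1.0, rtol=1e-9)


def test_gouy_chapman_sf_closed_form():
    """SF(z) = 1 − e^(−z/λ_D) for the linearised double-layer profile."""
    lam, sigma = 1.0, -0.02
    na, cl = _gc_profiles(lam, sigma)
    res = cf.screening_factor(na, cl, sigma)
    exact = 1.0 - np.exp(-res.d_grid / lam)
    assert np.abs(res.sf - exact).max() < 5e-4


def test_sf_nondecreasing_when_na_dominates():
    lam, sigma = 0.5, -0.02
    na, cl = _gc_profiles(lam, sigma)
    res = cf.screening_factor(na, cl, sigma)
    assert np.all(np.diff(res.sf) >= -1e-15)


def test_sf_errors():
    edges = np.arange(0, 1.01, 0.1)
    na = _profile(edges, np.full(10, 0.6))
    cl = _profile(np.arange(0, 2.02, 0.2), np.full(10, 0.6), "Cl-")
    with pytest.raises(GridError):
        cf.screening_factor(na, cl, -0.02)
    with pytest.raises(ValueError):
        cf.screening_factor(na, _profile(edges, np.full(10, 0.6), "Cl-"), 0.0)


def test_far_boundary_conservation(bath):
    """For an electroneutral frame SF(box edge) → (|σ| + |Q_DNA|)/|σ|."""
    sigma = -0.02
    surface = cf.SurfaceModel("flat", sigma=sigma)
    frames = [cf.generate_ion_configuration(
        surface, bath, dna=cf.DnaPlacement(geometry="flat"),
        box=(21.64, 12.5, 5.0), seed=200 + k) for k in range(8)]
    na = cf.bin_concentration(frames, "Na+", bin_width=0.05, d_max=5.0)
    cl = cf.bin_concentration(frames, "Cl-", bin_width=0.05, d_max=5.0)
    res = cf.screening_factor(na, cl, sigma)
    area = 21.64 * 12.5 * 1e-18
    q_dna = 22 * CONSTANTS.elementary_charge_e / area
    expected = (abs(sigma) + q_dna) / abs(sigma)
    # Poisson noise of the ion-count difference over 8 frames
    assert res.sf[-1] == pytest.approx(expected, rel=0.12)


# --- onset ----------------------------------------------------------------

def test_onset_closed_form_inversion():
    d = np.linspace(0, 5, 2001)
    res = cf.ScreeningResult(d_grid=d, sf=1 - np.exp(-d / 1.0), sigma=-0.02)
    onset = cf.screening_onset(res, 0.05)
    assert onset == pytest.approx(-np.log(0.95), abs=1e-5)


def test_onset_absent_when_never_reached():
    d = np.linspace(0, 5, 100)
    res = cf.ScreeningResult(d_grid=d, sf=np.zeros_like(d), sigma=-0.02)
    assert cf.screening_onset(res, 0.05) is None


# --- unscreened DNA charge ------------------------------------------------

def _dna_exponential_profile(rho0, a, d_max=6.0, width=0.002):
    edges = np.arange(0.0, d_max + width / 2, width)
    cen = 0.5 * (edges[:-1] + edges[1:])
    conc = rho0 * np.exp(-cen / a)  # mol/L of charge sites
    return _profile(edges, conc, "DNA_charge")


def test_fully_screened_gives_zero():
    prof = _dna_exponential_profile(1e-3, 0.5)
    res = cf.ScreeningResult(d_grid=prof.bin_edges,
                             sf=np.ones(prof.bin_edges.size), sigma=-0.02)
    assert cf.unscreened_dna_charge(prof, res) == 0.0


def test_unscreened_limit_gives_total():
    prof = _dna_exponential_profile(1e-3, 0.5)
    res = cf.ScreeningResult(d_grid=prof.bin_edges,
                             sf=np.zeros(prof.bin_edges.size), sigma=-0.02)
    total = (prof.concentration * MOLAR_TO_SI * CONSTANTS.avogadro_NA
             * prof.widths * NM_TO_M).sum()
    assert cf.unscreened_dna_charge(prof, res) == pytest.approx(total, rel=1e-12)


def test_exponential_layer_symbolic_integral():
    """Exponential DNA layer against SF = 1 − e^(−z/λ): the unscreened
    integral has the closed form ρ₀/(1/a + 1/λ) (per SI conversion)."""
    rho0, a, lam = 2e-3, 0.4, 0.8
    prof = _dna_exponential_profile(rho0, a)
    sf = 1.0 - np.exp(-prof.bin_edges / lam)
    res = cf.ScreeningResult(d_grid=prof.bin_edges, sf=sf, sigma=-0.02)
    got = cf.unscreened_dna_charge(prof, res)
    rate = 1.0 / a + 1.0 / lam  # nm^-1
    exact = (rho0 * MOLAR_TO_SI * CONSTANTS.avogadro_NA
             * (1.0 - np.exp(-rate * 6.0)) / (rate / NM_TO_M))
    assert got == pytest.approx(exact, rel=5e-3)


# --- potential ------------------------------------------------------------

def test_zero_charge_zero_potential():
    edges = np.arange(0, 5.001, 0.01)
    pot = cf.potential_profile(np.zeros(edges.size - 1), edges, 1e-16)
    assert np.all(pot.v == 0.0)


def test_charged_sheet_parallel_plate_closed_form():
    """Single sheet Q at z = a: V(z) = −Q (z − a)/(A ε₀) beyond it."""
    A, Q, a = 1e-16, 1e-18, 2.0
    edges = np.arange(0.0, 10.0001, 0.005)
    q = np.zeros(edges.size - 1)
    idx = np.searchsorted(edges, a)
    q[idx] = Q
    sheet_z = 0.5 * (edges[idx] + edges[idx + 1])
    pot = cf.potential_profile(q, edges, A)
    z = pot.d_grid
    sel = z > 3.0
    exact = -Q * (z[sel] - sheet_z) * NM_TO_M / (A * CONSTANTS.vacuum_permittivity_eps0)
    np.testing.assert_allclose(pot.v[sel], exact, rtol=1e-3)


def test_neutral_dipolar_layer_plateaus():
    """A net-neutral ± exponential double layer has constant V beyond it."""
    A = 1e-16
    edges = np.arange(0.0, 10.0001, 0.005)
    cen = 0.5 * (edges[:-1] + edges[1:])
    # layer placed away from the integration boundary (starts at z = 1)
    s = np.maximum(cen - 1.0, 0.0)
    q = np.where(cen >= 1.0,
                 (np.exp(-s / 0.3) / 0.3 - np.exp(-s / 0.8) / 0.8), 0.0) \
        * 1e-19 * 0.005
    q[np.searchsorted(edges, 1.0)] -= q.sum()  # exactly neutral
    pot = cf.potential_profile(q, edges, A)
    drop = pot.v[-1] - pot.v[0]
    assert abs(pot.v[-1] - pot.v[int(0.85 * len(cen))]) < 1e-3 * abs(drop)


def test_nonuniform_grid_rejected():
    edges = np.array([0.0, 0.1, 0.3, 0.6])
    with pytest.raises(ValueError):
        cf.potential_profile(np.zeros(3), edges, 1e-16)


# --- Debye length ---------------------------------------------------------

def test_physiological_debye_length():
    params = cf.debye_length(0.150, 298.15, 78.5)
    assert params.debye_length == pytest.approx(0.78, abs=0.02)
    assert params.debye_length < 1.0


@given(st.floats(min_value=0.01, max_value=2.0),
       st.floats(min_value=250.0, max_value=350.0))
def test_quadrupled_ionic_strength_halves_debye_length(ionic, temp):
    lam1 = cf.debye_length(ionic, temp).debye_length
    lam4 = cf.debye_length(4 * ionic, temp).debye_length
    assert lam4 == pytest.approx(lam1 / 2, rel=1e-12)


def test_md_bath_concentration_ratio():
    lam06 = cf.debye_length(0.6).debye_length
    lam12 = cf.debye_length(1.2).debye_length
    assert lam06 / lam12 == pytest.approx(np.sqrt(2), rel=1e-12)


# --- capacitance ----------------------------------------------------------

def _gc_potential(sigma, eps_r=78.5, conc=0.6, width=0.002):
    lam = cf.debye_length(conc, 298.15, eps_r).debye_length
    A = 1e-16
    edges = np.arange(-0.1, 6.0001, width)
    cen = 0.5 * (edges[:-1] + edges[1:])
    rho = np.where(cen > 0,
                   (-sigma / (lam * NM_TO_M)) * np.exp(-np.maximum(cen, 0) / lam),
                   0.0)
    q = rho * A * width * NM_TO_M
    q[np.searchsorted(edges, 0.0)] += -q.sum()
    return cf.potential_profile(q, edges, A, relative_permittivity=eps_r), lam


def test_capacitance_matches_gouy_chapman():
    sigma = -0.02
    pot, lam = _gc_potential(sigma)
    c_eff = cf.capacitance_from_profile(pot, sigma, surface_z=0.0)
    exact = (CONSTANTS.vacuum_permittivity_eps0 * 78.5) / (lam * NM_TO_M)
    assert c_eff == pytest.approx(exact, rel=0.02)
    assert pot.plateau_ok


def test_capacitance_linear_response_invariance():
    pot1, _ = _gc_potential(-0.02)
    pot2, _ = _gc_potential(-0.04)
    c1 = cf.capacitance_from_profile(pot1, -0.02, surface_z=0.0)
    c2 = cf.capacitance_from_profile(pot2, -0.04, surface_z=0.0)
    assert c2 == pytest.approx(c1, rel=0.02)
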