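"""Generator checks: Gouy–Chapman structure, electroneutrality,
determinism, DNA track geometry, transfer-curve and dose generators."""

import numpy as np
import pytest
from scipy import stats

import crumplefet as cf
from crumplefet.screening import debye_length, surface_potential_linear
from crumplefet.surfaces import surface_geometry
from crumplefet.synthetic import CapacityError, generate_ion_configuration

BOX = (21.64, 12.5, 5.0)


def test_zero_field_ions_uniform(bath):
    """With sigma = 0 and no DNA the ion density is uniform in z."""
    surface = cf.SurfaceModel("flat", sigma=0.0)
    frame = generate_ion_configuration(surface, bath, box=BOX, seed=11)
    z = frame.select("Na+")[:, 2]
    z = z[(z >= 0.2) & (z < 4.7)]
    counts, _ = np.histogram(z, bins=10, range=(0.2, 4.7))
    chi2 = stats.chisquare(counts)
    assert chi2.pvalue > 0.01


def test_counter_ion_profile_matches_gouy_chapman(bath):
    """Binned Na+ profile near a charged flat wall follows the
    linearised Gouy–Chapman closed form (3 SE per bin, one multiplicity
    exception allowed over the d in [0.2, 3] nm window)."""
    surface = cf.SurfaceModel("flat", sigma=-0.02)
    frames = [generate_ion_configuration(surface, bath, box=BOX, seed=100 + k)
              for k in range(20)]
    prof = cf.bin_concentration(frames, "Na+", bin_width=0.1, d_max=3.0)
    debye = debye_length(bath.bulk_concentration, bath.temperature,
                         bath.relative_permittivity)
    psi0 = surface_potential_linear(surface.sigma, debye)
    beta_e = (cf.CONSTANTS.elementary_charge_e
              / (cf.CONSTANTS.boltzmann_kB * bath.temperature))
    d = prof.centers
    expected = bath.bulk_concentration * np.exp(
        -beta_e * psi0 * np.exp(-d / debye.debye_length))
    sel = d >= 0.2
    # Poisson SE per bin from the expected mean counts
    vol_l = prof.bin_volume * 1e-24 * len(frames)
    exp_counts = expected * cf.CONSTANTS.avogadro_NA * vol_l
    se = np.sqrt(exp_counts) / (cf.CONSTANTS.avogadro_NA * vol_l)
    obs = prof.concentration
    n_out = int((np.abs(obs[sel] - expected[sel]) > 3 * se[sel]).sum())
    assert n_out <= 1


def test_probe_sequence_yields_22_backbone_sites(flat_surface):
    dna = cf.DnaPlacement()  # default probe sequence
    assert len(dna.sequence) == 22
    sites = cf.dna_charge_sites(dna, flat_surface, (12.5, 12.5, 5.0))
    assert sites.shape == (22, 3)
    frame = generate_ion_configuration(cf.SurfaceModel("flat"),
                                       cf.IonBathSpec(seed=2), dna=dna)
    assert frame.counts()["DNA_charge"] == 22
    assert frame.charge_per_species["DNA_charge"] == -1.0


@pytest.mark.parametrize("kind,geometry,ok", [
    ("flat", "flat", True),
    ("sinusoid", "concave", True),
    ("sinusoid", "convex", True),
    ("sinusoid", "across", True),
    ("trench", "trench_bottom", True),
    ("flat", "concave", False),
    ("sinusoid", "trench_bottom", False),
])
def test_dna_geometry_surface_compatibility(kind, geometry, ok):
    surface = cf.SurfaceModel(kind)
    dna = cf.DnaPlacement(geometry=geometry)
    if ok:
        sites = cf.dna_charge_sites(dna, surface, (21.64, 12.5, 5.0))
        d = cf.surface_distance(sites, surface)
        assert np.all(d > 0)
        np.testing.assert_allclose(d, dna.standoff, atol=0.02)
    else:
        with pytest.raises(ValueError):
            cf.dna_charge_sites(dna, surface, (21.64, 12.5, 5.0))


@pytest.mark.parametrize("kind,dna_geom", [
    ("flat", None), ("flat", "flat"), ("sinusoid", "concave"),
    ("trench", "trench_bottom"),
])
def test_electroneutrality_within_one_charge(bath, kind, dna_geom):
    surface = cf.SurfaceModel(kind, sigma=-0.02)
    dna = cf.DnaPlacement(geometry=dna_geom) if dna_geom else None
    frame = generate_ion_configuration(surface, bath, dna=dna, box=BOX, seed=5)
    total = (frame.total_charge_e()
             + surface.sigma * surface.area_A
             / cf.CONSTANTS.elementary_charge_e)
    assert abs(total) <= 1.0


def test_seed_determinism(bath):
    surface = cf.SurfaceModel("sinusoid", sigma=-0.02)
    a = generate_ion_configuration(surface, bath, box=BOX, seed=9)
    b = generate_ion_configuration(cf.SurfaceModel("sinusoid", sigma=-0.02),
                                   bath, box=BOX, seed=9)
    np.testing.assert_array_equal(a.positions, b.positions)
    assert list(a.species) == list(b.species)


def test_tiny_box_raises_capacity_error(bath):
    with pytest.raises(CapacityError):
        generate_ion_configuration(cf.SurfaceModel("flat"), bath,
                                   box=(5.0, 5.0, 0.3), seed=0)


def test_concave_valley_depletion(bath):
    """Counter-ions within 0.3 nm of the surface are rarer above valley
    bottoms than above crests (concave ion exclusion)."""
    surface = cf.SurfaceModel("sinusoid", sigma=-0.02)
    wl = surface.wavelength
    valley_n = crest_n = 0
    for k in range(4):
        frame = generate_ion_configuration(
            cf.SurfaceModel("sinusoid", sigma=-0.02), bath,
            box=(4 * wl, 50.0, 5.0), seed=40 + k)
        na = frame.select("Na+")
        d, _ = surface_geometry(na, surface)
        xm = np.mod(na[:, 0], wl)
        near = d < 0.3
        valley_n += int((near & (np.abs(xm - wl / 2) < wl / 8)).sum())
        crest_n += int((near & ((xm < wl / 8) | (xm > wl - wl / 8))).sum())
    assert crest_n > 30  # enough statistics for the comparison
    assert valley_n < 0.75 * crest_n


# --- transfer-curve generator --------------------------------------------

def test_noiseless_curve_minimum_on_grid():
    curve = cf.generate_transfer_curve(0.30, noise_sd=0.0)
    assert curve.v_gs[np.argmin(curve.i_ds)] == pytest.approx(0.30, abs=1e-9)


def test_dirac_window_matches_measured_devices():
    curve = cf.generate_transfer_curve(0.25, noise_sd=0.0)
    v_min = curve.v_gs[np.argmin(curve.i_ds)]
    assert 0.0 <= v_min <= 0.5


def test_constructed_dirac_offset_recovered():
    grid_step = 1.5 / 300
    a = cf.generate_transfer_curve(0.300, noise_sd=0.0)
    b = cf.generate_transfer_curve(0.320, noise_sd=0.0)
    da = cf.extract_dirac_point(a).v_dirac
    db = cf.extract_dirac_point(b).v_dirac
    assert db - da == pytest.approx(0.020, abs=grid_step)


def test_nonpositive_branch_slope_rejected():
    with pytest.raises(ValueError):
        cf.generate_transfer_curve(0.3, params={"k_h": 0.0})


# --- dose-response generator ----------------------------------------------

def test_sips_saturation_limit():
    # Langmuir case: C = 1e6/K saturates to dv_max within 0.1%
    shift = float(cf.sips_shift(1e6 / 3e13, 180.0, 3e13, 1.0))
    assert shift == pytest.approx(180.0, rel=1e-3)
    # heterogeneous case: (KC)^a >= 1e3 gives the same bound
    sp = cf.SipsParams(noise_sd=0.0, n_replicates=1)
    c_sat = 10.0 ** (3.0 / sp.heterogeneity_a) / sp.affinity_K
    shift = float(cf.sips_shift(c_sat, sp.dv_max, sp.affinity_K,
                                sp.heterogeneity_a))
    assert shift == pytest.approx(sp.dv_max, rel=1e-3)


def test_sips_half_saturation_identity():
    shift = float(cf.sips_shift(1.0 / 3e13, 180.0, 3e13, 1.0))
    assert shift == pytest.approx(90.0, abs=1e-12)


def test_dose_table_reproducible_and_controls_flagged():
    sp = cf.SipsParams(seed=7)
    concs = [2e-18, 2e-16, 2e-14]
    a = cf.generate_dose_response(sp, concs)
    b = cf.generate_dose_response(cf.SipsParams(seed=7), concs)
    assert a.table.equals(b.table)
    nc = a.negative_controls()
    assert len(nc) == sp.n_replicates
    assert (nc["concentration"] == 0).all()
    with pytest.raises(ValueError):
        cf.generate_dose_response(sp, [0.0, 2e-16])
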