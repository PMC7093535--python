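# Methods

`crumplefet` models the signal chain of a crumpled-graphene field-effect
(FET) nucleic-acid sensor: how the electrolyte screens adsorbed DNA
charge near a deformed sensing surface, how the unscreened charge moves
the transistor's Dirac point, and how the dose–response of that shift is
fitted and turned into a limit of detection.  This note records the
models, the parameters that matter, the numerical choices, and what the
synthetic-data generator does and does not capture.

## Electrostatics of the double layer

**Debye length.**  For a symmetric 1:1 electrolyte of ionic strength
*I* (mol L⁻¹) at temperature *T* with relative permittivity ε_r,

    λ_D = sqrt(ε₀ ε_r k_B T / (2 N_A e² · 10³ I)),

reported in nm.  At physiological strength (0.15 M, 298 K, ε_r = 78.5)
λ_D ≈ 0.79 nm; it halves when *I* quadruples.

**Screening factor.**  Given sodium and chloride molar concentration
profiles against the distance *z* from the surface, the screening factor

    SF(z) = ∫₀ᶻ F ([Na⁺] − [Cl⁻]) dz′ / |σ|

measures the cumulative net ionic charge per projected area between the
surface and *z*, normalised by the surface charge density σ (F is the
Faraday constant; concentrations enter in SI).  SF = 1 means the surface
charge is fully screened.  Because binned profiles are piecewise
constant, the integral is evaluated exactly per bin; SF(0) = 0 by
construction.  The raw statistic is *not* clamped — with adsorbed DNA in
the system it exceeds 1 at the far boundary, where it must equal
(|σ| + |Q_DNA|/A)/|σ| for an electroneutral system (a conservation check
used in the tests).  The *screening onset* is the smallest distance where
SF reaches a threshold (default 0.05, exposed as a parameter; the
threshold mirrors the "screening starts here" annotation common in
double-layer profile figures, which is qualitative).

**Unscreened DNA charge.**  The adsorbed backbone charge not yet
neutralised by intervening counter-ions is

    N_unscreened = ∫ ρ_DNA(z) · (1 − min(SF(z), 1)) dz,

in elementary charges per device area.  SF is clamped to [0, 1] only
inside this weighting, and the result is clamped to the total adsorbed
charge.  The weighting itself is a modelling choice: it treats screening
as complete wherever the cumulative counter-charge has matched the
surface charge.

**Potential profile.**  From a per-bin net charge profile q(z) on a
uniform grid, V(z) = −∬_{z₀}^{z} q(z′)/(A ε) dz′ dz′ by two cumulative
trapezoids on the bin-centre grid, with V(z₀) = 0 and V′(z₀) = 0.  ε
defaults to ε₀ (appropriate when q includes an explicit solvent); for
the implicit-solvent synthetic frames the bath's ε₀ε_r is used instead —
the solvent's polarisation is not part of q there.  The capacitance
proxy is C_eff = |σ|/|V(surface) − V(bulk)|, with the bulk potential
taken as the mean over the last 10 % of the grid and a flag raised if
the potential is still drifting there.  For a linearised diffuse layer
this recovers ε₀ε_r/λ_D to within 2 %.

## Synthetic particle configurations

The generator replaces molecular dynamics: it samples ion positions from
a *linear-response mean-field model* so that every downstream statistic
has a closed-form oracle on flat surfaces.

- Surface potential ψ(d) = ψ₀ e^(−d/λ_D) in the distance-from-surface
  coordinate *d*, with ψ₀ = σ λ_D/(ε₀ ε_r) (linearised Grahame).
- Boltzmann weights exp(∓e ψ/k_BT) for Na⁺/Cl⁻, realised by rejection
  sampling of uniform proposals.
- A hard exclusion of ion centres within 0.15 nm of the surface
  manifold.
- Screened-Coulomb site potentials from each DNA backbone charge,
  ψ_site(r) = −e·e^(−r/λ_D)/(4π ε₀ ε_r r), evaluated no closer than the
  steric ion–DNA contact (0.3 nm, inside which ions are excluded).
  Without these terms the counter-ions that compensate the DNA would
  spread uniformly over the box instead of localising around the
  strand, and the relative geometry of DNA and ions — the heart of the
  concave-hot-spot mechanism — would be lost.
- A **concave confinement penalty** u(d) = ε_c·(κ⁺ R_c)·e^(−d/R_c) with
  ε_c = 5 k_BT and R_c = 0.7 nm (a hydrated-ion diameter), where κ⁺ is
  the surface curvature toward the fluid where the surface is concave
  and zero elsewhere.  This term encodes the fact that hydrated ions
  cannot pack into concave nanoscale valleys; it is what displaces the
  counter-ion cloud outward there.  It is needed because hard-core
  exclusion alone provably does not alter the globally binned double
  layer of a periodic corrugation: the concave and convex shell-volume
  factors (1 ∓ κd) integrate to zero over a period, so without an
  explicit confinement term flat and crumpled surfaces would have
  identical distance-binned profiles.  Flat surfaces (κ⁺ = 0) are
  untouched, which preserves all flat closed-form oracles.

Ion counts default to the bulk-density expectation over the accessible
volume (estimated from the proposal cloud), after which the Na⁺/Cl⁻
split is adjusted so that ion charge + DNA charge + σ·A vanishes to
within one elementary charge.  The default surface charge density is
σ = −0.02 C m⁻², for which eψ₀/k_BT ≈ 0.44 at 0.6 M — inside the
linear-response regime the model assumes.  (At several-fold larger |σ|
the exponential weights depart from the linear profile enough that the
electroneutrality adjustment distorts the far field.)

The DNA track lays one −1e site per base (22 for the default 22-mer
probe, sequence AACCACACAACCTACTACCTCA) at a 0.7 nm rise along the
adsorption geometry — flat, concave (valley line), convex (crest line),
across the corrugation, or along the bottom of a half-cylinder trench
groove — at a 0.35 nm stand-off (a typical π-stacking gap; the true
stand-off per geometry is not known and the parameter is exposed).

**What the generator does not capture.**  No explicit water (so no
layering or dielectric saturation), no ion–ion correlations, no
nonlinear Poisson–Boltzmann response, no DNA conformational sampling,
and the confinement penalty is a one-parameter stand-in for the real
free-energy cost of dehydration.  Passing tests therefore demonstrate
that the *analysis chain* is correct and that the *model class*
reproduces the qualitative physics (concave exclusion, its effect on
screening onset, unscreened charge and capacitance) — not that the
quantitative MD or experimental values would be reproduced.

## Flat-vs-concave comparisons

The two directional findings are computed on globally binned profiles
(projected-slab normalisation, the planar convention) averaged over 32
seeded frames per system in a 21.6 × 50 × 5 nm box at 0.6 M:

1. With the same 22-mer adsorbed flat vs along a valley, the screening
   onset is farther out and the unscreened-DNA fraction larger for the
   concave system.
2. At matched σ without DNA, the double-layer capacitance proxy is
   lower for the crumpled surface (its diffuse layer is displaced
   outward), typically by a factor 1.2–2.

A per-window (valley-only) analysis was considered and rejected: the
counter-ions that belong to the DNA concentrate inside any window that
contains the strand, while the SF normalisation |σ| sees only the
window's share of surface charge, so windowed SF curves are inflated by
construction and do not compare cleanly across geometries.

Statistical resolution: with the default frame counts the
unscreened-fraction margin is ≈ +0.03…+0.06 and the onset margin
≈ +0.001…+0.010 nm against a per-run standard error of a few 10⁻³ nm —
the onset direction is resolved at roughly the 2σ level and can come
out reversed for an occasional seed; the fraction and capacitance
directions are more robust.  Frame counts are parameters, so users
needing sharper comparisons can raise them.

## Carrier model and hot spots

The Dirac-point shift is ΔV_D = e Δn/C_T with Δn = α·N_unscreened
(coupling α ∈ (0,1], default 1) and C_T the electrolyte-gate capacitance
per area.  Deformation can open a bandgap E_g; mobility follows
μ ∝ E_g^(−3/2), and the carrier density is taken to respond inversely to
mobility.  The *hot-spot mixture* treats the channel as an area-weighted
parallel combination of a background (gap 0.4224 eV) and hot-spot
regions (gap 1.7641 eV, the gap with an adsorbed adenine); a hot spot
of area fraction f carries an induced charge density (default
1.12 × 10¹⁸ e m⁻², i.e. 22 charges over a ~2.45 × 8 nm trench footprint)
whose carrier response is amplified by the inverse mobility ratio
(E_hot/E_bg)^(3/2) ≈ 8.5.  The minimal f reaching a target shift is
found by bisection (relative tolerance 10⁻⁶); the model identifier and
every parameter are echoed into the result.  This mixture is an explicit
**reconstruction** — the published account gives the ingredients (the
ΔV_D relation, the μ–E_g law, the two gaps) and the conclusion (a
~10⁻⁹ area fraction suffices), not the intermediate algebra.  With the
defaults above, a 12 mV target yields f ≈ 8 × 10⁻⁵ % — reproducing the
~10⁻⁷ % figure is a stretch goal that would require the unpublished
coupling values, and no acceptance check depends on it.

## Transfer curves and dose–response

**Dirac extraction.**  Moving-average smooth (5 points), grid argmin,
then a parabola fit over a ±0.1 V index-based window around the argmin
(index-based so the estimator is exactly translation-covariant on a
uniform grid).  Ties resolve to the smallest voltage and are flagged;
minima at the sweep edge raise an error.  On synthetic V-shaped sweeps
(301 points over −0.5…1 V) with 1 % current noise the vertex is
recovered within 5 mV in ≥ 95 % of runs.

**Sips isotherm.**  |ΔV|(C) = ΔV_max (KC)^a / (1 + (KC)^a) — the
Langmuir–Freundlich binding model; a = 1 recovers Langmuir.  Fitting is
multi-start nonlinear least squares (lmfit/Levenberg–Marquardt) in
(ΔV_max, log₁₀K, a) with a ∈ (0, 2]; starts span the measured
concentration decades.  Residuals are unweighted by default: the
modelled measurement noise is additive in the shift, so ordinary least
squares is the calibrated choice (Monte-Carlo: ±2 SE covers the truth
for ~93–94 % of seeded tables per parameter); relative-residual
weighting is available as an option for heteroscedastic data.  K's
standard error is delta-method derived from log₁₀K's.

**Synthetic dose tables.**  The generator's default truth —
ΔV_max = 180 mV, K = 3 × 10¹³ L mol⁻¹, a = 0.35, noise 3 mV, 3
replicates over 2 aM…20 nM — was chosen so the noiseless isotherm
reproduces the reported crumpled-device response: ~180 mV total shift,
≈ 12 mV at 20 aM, and a-few-mV signals at 2 aM that sit inside a 3 mV
negative-control band.

**Limit of detection.**  A concentration is detected when its mean
|shift| exceeds mean + k·SD of the negative-control |shifts|
(default k = 3), and the LOD is the lowest tested concentration that is
detected *with all higher concentrations also detected* — the
persistence requirement discounts single-point excursions, matching the
practice of rejecting signals that overlap the control band.  On tables
generated at the default conditions the LOD comes out at 20 aM
(≈ 600 molecules in 50 µL) when the 2 aM signal is inside the band, and
the marginal 2 aM case genuinely flips with the noise seed — as it did
between devices in the experiments this emulates.

## Numerical choices

- Distances to the sinusoidal surface: coarse 129-point grid search over
  ±0.75 λ plus 40 vectorised golden-section iterations (≲10⁻⁹ nm
  bracket); validated against brute-force surface sampling to 10⁻³ nm.
- Accessible shell volumes for corrugated surfaces: seeded Monte-Carlo
  (default 2 × 10⁵ points, seed 1234); flat slabs are exact.
- Default profile bins 0.05 nm to 5 nm (resolves the sub-nm double
  layer); SF integration is exact for binned data; potential integration
  uses uniform grids only and refuses others.
- Degenerate inputs: empty frames give zero profiles (not errors); zero
  accessible-volume bins are flagged undefined; σ = 0 makes SF
  normalisation an error; a gapless mobility ratio is a domain error
  pointing to the mixture's background term.
- Seeds: every stochastic routine takes an explicit seed; identical
  seeds give bit-identical outputs.

## Known limitations

- The linear-response sampler cannot produce nonlinear saturation of
  the double layer at strongly charged surfaces.
- The trench geometry is a half-cylinder groove; the cited narrow-trench
  system modelled the crevice with a carbon nanotube.
- Water's contribution to the net charge q(z) — present in explicit-
  solvent simulations — is absent; potentials from synthetic frames use
  ε₀ε_r instead.
- The hot-spot mixture's induced-charge and capacitance defaults set the
  absolute scale of the area fraction; only its ordering properties are
  validated.
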