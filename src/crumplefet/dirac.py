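"""Carrier model: from unscreened adsorbed charge to Dirac-point shift,
and the bandgap–mobility hot-spot mixture that rationalises attomolar
sensitivity.

The core relation is ΔV_D = e Δn / C_T, with the carrier-density change
Δn proportional to the unscreened adsorbed DNA charge density.  Deformed
regions of the channel can open a bandgap E_g; mobility falls as
μ ∝ E_g^(−3/2), and because the carrier density responds inversely to
mobility, a small "hot-spot" area fraction with a wide gap amplifies the
response to a few adsorbed charges.  The mixture equation used here is a
declared reconstruction (see ``MIXTURE_MODEL_VERSION``), not a measured
device model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional

from .constants import CONSTANTS
from .datatypes import BandgapMixture

MIXTURE_MODEL_VERSION = "parallel-mixture/1"

#: reconstruction defaults: gate capacitance per area (F m⁻²) and the
#: induced carrier density inside a hot spot from one adsorbed 22-mer
#: (22 e over a trench footprint of ~2.45 × 8 nm²)
DEFAULT_MIXTURE_PARAMS = {
    "c_total": 1e-2,           # F m^-2, electrolyte-gate capacitance scale
    "induced_charge": 1.12e18,  # e m^-2 inside a hot spot
    "coupling_alpha": 1.0,
}


def dirac_shift_from_charge(delta_n: float, c_total: float) -> float:
    """Dirac-point shift ΔV_D = e Δn / C_T, in volts.

    delta_n is the carrier-density change in m⁻², c_total the total gate
    capacitance per area in F m⁻².
    """
    if not c_total > 0:
        raise ValueError("c_total must be > 0")
    return CONSTANTS.elementary_charge_e * delta_n / c_total


def delta_n_from_unscreened(n_dna_unscreened: float,
                            coupling_alpha: float = 1.0) -> float:
    """Carrier-density change Δn = α · N_DNA^unscreened (m⁻²)."""
    if not 0 < coupling_alpha <= 1:
        raise ValueError("coupling_alpha must be in (0, 1]")
    return coupling_alpha * n_dna_unscreened


def mobility_ratio(eg_from: float, eg_to: float) -> float:
    """Mobility factor μ(eg_to)/μ(eg_from) under μ ∝ E_g^(−3/2)."""
    if eg_from <= 0 or eg_to <= 0:
        raise ValueError(
            "mobility_ratio is undefined at zero gap (gapless graphene); "
            "use the mixture model's background term for ungapped regions")
    return (eg_to / eg_from) ** (-1.5)


@dataclass
class HotspotSolution:
    """Minimal hot-spot area fraction with the full model echo."""

    area_fraction_f: float
    target_shift: float  # V
    mixture: BandgapMixture
    model: str = MIXTURE_MODEL_VERSION
    params: dict = field(default_factory=dict)
    assumptions: str = ("channel response = area-weighted parallel mixture of "
                        "background and hot-spot regions; hot-spot carrier "
                        "response amplified by the inverse mobility ratio "
                        "(E_g,hot/E_g,bg)^(3/2); carrier density taken "
                        "inversely related to mobility")


def _default_mixture_shift(f: float, mixture: BandgapMixture,
                           params: Mapping) -> float:
    """Dirac shift (V) of the area-weighted mixture at hot-spot fraction f.

    Hot spots carry an induced charge density whose carrier response is
    amplified by the inverse mobility ratio between background and
    hot-spot gaps; the background area contributes no shift without
    adsorbed charge.
    """
    gain = 1.0 / mobility_ratio(mixture.eg_background, mixture.eg_hotspot)
    delta_n = f * gain * params["coupling_alpha"] * params["induced_charge"]
    return dirac_shift_from_charge(delta_n, params["c_total"])


def hotspot_area_fraction(target_shift: float,
                          mixture: Optional[BandgapMixture] = None,
                          model_params: Optional[Mapping] = None,
                          model_fn: Callable = _default_mixture_shift,
                          rtol: float = 1e-6) -> HotspotSolution:
    """Minimal area fraction f whose mixture shift reaches ``target_shift``.

    Solved by bisection on [0, 1] to relative tolerance ``rtol``; the
    model must be monotone (weakly increasing) in f.  Raises when the
    target is unreachable even at f = 1, naming the binding parameters.
    """
    if target_shift < 0:
        raise ValueError("target_shift must be >= 0")
    mixture = mixture or BandgapMixture()
    params = dict(DEFAULT_MIXTURE_PARAMS)
    params.update(model_params or {})

    if target_shift == 0.0:
        return HotspotSolution(0.0, 0.0, mixture, params=params)

    if model_fn(1.0, mixture, params) < target_shift:
        raise ValueError(
            f"target shift {target_shift} V unreachable at f = 1; binding "
            f"parameters: induced_charge={params['induced_charge']:g} e/m^2, "
            f"c_total={params['c_total']:g} F/m^2, gaps "
            f"{mixture.eg_background}->{mixture.eg_hotspot} eV")

    lo, hi = 0.0, 1.0
    while (hi - lo) > rtol * max(hi, 1e-300):
        mid = 0.5 * (lo + hi)
        if model_fn(mid, mixture, params) >= target_shift:
            hi = mid
        else:
            lo = mid
    return HotspotSolution(hi, target_shift, mixture, params=params)
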