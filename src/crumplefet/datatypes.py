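"""Core data containers shared across the analysis chain."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np
import pandas as pd

from .surfaces import SurfaceModel

KNOWN_SPECIES = ("Na+", "Cl-", "DNA_charge", "surface_atom", "other")

#: default charge (units of e) per species label
DEFAULT_CHARGES: Dict[str, float] = {
    "Na+": 1.0,
    "Cl-": -1.0,
    "DNA_charge": -1.0,
    "surface_atom": 0.0,
    "other": 0.0,
}


@dataclass
class ParticleFrame:
    """Labelled charged-particle configuration near a model surface.

    positions are in nm; ``box`` is the (lx, ly, lz) fluid box with the
    mean surface plane at z = 0 and solution at z > 0 (corrugated surfaces
    dip below 0).  Charges are per species, in units of e.
    """

    positions: np.ndarray
    species: np.ndarray
    charge_per_species: Dict[str, float]
    box: np.ndarray
    surface: Optional[SurfaceModel] = None

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        if self.positions.size == 0:
            self.positions = self.positions.reshape(0, 3)
        self.species = np.asarray(self.species, dtype=object)
        self.box = np.asarray(self.box, dtype=float)
        if self.positions.shape[0] != self.species.shape[0]:
            raise ValueError("positions and species lengths differ")
        if self.positions.size and not np.isfinite(self.positions).all():
            raise ValueError("non-finite coordinates in frame")
        missing = set(np.unique(self.species)) - set(self.charge_per_species)
        if missing:
            raise KeyError(f"species without a defined charge: {sorted(missing)}")

    def __len__(self) -> int:
        return self.positions.shape[0]

    def select(self, species: str) -> np.ndarray:
        """Positions of one species, (n, 3) nm."""
        return self.positions[self.species == species]

    def counts(self) -> Dict[str, int]:
        labels, n = np.unique(self.species, return_counts=True)
        return dict(zip(labels.tolist(), n.tolist()))

    def total_charge_e(self) -> float:
        """Total mobile+DNA particle charge in units of e (excludes σ·A)."""
        return float(sum(self.charge_per_species[s] * n for s, n in self.counts().items()))


@dataclass
class TransferCurve:
    """Gate-voltage sweep of drain–source current (ambipolar I–V)."""

    v_gs: np.ndarray
    i_ds: np.ndarray
    v_ds: float = 0.05
    label: str = ""

    def __post_init__(self) -> None:
        self.v_gs = np.asarray(self.v_gs, dtype=float)
        self.i_ds = np.asarray(self.i_ds, dtype=float)
        if self.v_gs.shape != self.i_ds.shape:
            raise ValueError("v_gs and i_ds lengths differ")
        if self.v_gs.size < 5:
            raise ValueError("transfer curve needs at least 5 points")
        if not np.all(np.diff(self.v_gs) > 0):
            raise ValueError("v_gs must be strictly increasing")
        if not (np.isfinite(self.i_ds).all() and np.all(self.i_ds > 0)):
            raise ValueError("i_ds must be finite and positive")

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.v_gs, self.i_ds * 1e6, label=self.label or None)
        ax.set_xlabel("$V_{gs}$ (V)")
        ax.set_ylabel("$I_{ds}$ (µA)")
        return ax


@dataclass
class DoseResponse:
    """Dirac-shift vs concentration table with negative-control replicates.

    Backed by a DataFrame with columns ``concentration`` (mol L⁻¹, zero for
    negative controls), ``shift_mV``, ``replicate_id`` and
    ``is_negative_control``.
    """

    table: pd.DataFrame

    REQUIRED = ("concentration", "shift_mV", "replicate_id", "is_negative_control")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise KeyError(f"dose table missing columns: {missing}")
        if (self.table["concentration"] < 0).any():
            raise ValueError("concentrations must be >= 0")

    @property
    def fitting_eligible(self) -> bool:
        """At least two distinct positive concentrations are required to fit."""
        pos = self.table.loc[~self.table["is_negative_control"], "concentration"]
        return pos[pos > 0].nunique() >= 2

    def positive(self) -> pd.DataFrame:
        t = self.table
        return t[(~t["is_negative_control"]) & (t["concentration"] > 0)]

    def negative_controls(self) -> pd.DataFrame:
        return self.table[self.table["is_negative_control"]]


@dataclass
class ConcentrationProfile:
    """Molar concentration vs distance-from-surface, one species."""

    bin_edges: np.ndarray
    species: str
    concentration: np.ndarray  # mol L^-1 per bin
    bin_volume: np.ndarray  # nm^3 per bin (accessible or slab, per builder)
    frame_count: int = 1
    undefined_bins: Optional[np.ndarray] = None  # zero accessible volume

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.concentration = np.asarray(self.concentration, dtype=float)
        self.bin_volume = np.asarray(self.bin_volume, dtype=float)
        if not np.all(np.diff(self.bin_edges) > 0):
            raise ValueError("bin_edges must be strictly increasing")
        if (self.concentration < 0).any():
            raise ValueError("concentrations must be nonnegative")

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def widths(self) -> np.ndarray:
        return np.diff(self.bin_edges)

    def same_grid(self, other: "ConcentrationProfile", tol: float = 1e-9) -> bool:
        return (self.bin_edges.shape == other.bin_edges.shape
                and np.allclose(self.bin_edges, other.bin_edges, atol=tol))


@dataclass
class ConcentrationMap2D:
    """y-averaged molar concentration on an (x, z) grid, one species."""

    x_edges: np.ndarray
    z_edges: np.ndarray
    concentration: np.ndarray  # (nx, nz), mol L^-1
    species: str

    def __post_init__(self) -> None:
        if (np.asarray(self.concentration) < 0).any():
            raise ValueError("map concentrations must be nonnegative")


@dataclass
class ScreeningResult:
    """Screening factor SF as a function of distance from the surface."""

    d_grid: np.ndarray  # nm, starts at 0
    sf: np.ndarray  # dimensionless
    sigma: float  # C m^-2 used for normalisation
    onset_distance: Optional[float] = None
    n_dna_unscreened: Optional[float] = None  # e per m^2


@dataclass
class PotentialProfile:
    """Electrostatic potential from the doubly integrated charge profile."""

    d_grid: np.ndarray  # nm
    v: np.ndarray  # volts
    reference_z0: float
    area_A: float
    plateau_ok: bool = True


@dataclass
class DebyeParams:
    ionic_strength: float  # mol L^-1
    temperature: float  # K
    relative_permittivity: float
    debye_length: float  # nm

    def __post_init__(self) -> None:
        if not self.debye_length > 0:
            raise ValueError("debye_length must be > 0")


@dataclass
class DiracEstimate:
    v_dirac: float  # V
    i_min: float  # A
    window_used: tuple
    method: str = "smoothed-argmin+parabola"
    tie_flag: bool = False


@dataclass
class ShiftSeries:
    """Dirac shifts (mV) per condition relative to a baseline."""

    condition: list
    shift_mV: np.ndarray
    uncertainty: np.ndarray  # replicate SD, mV (0 where single)
    baseline: str = ""


@dataclass
class LodEstimate:
    lod_concentration: Optional[float]  # mol L^-1, None when undetermined
    criterion: str
    nc_mean: float
    nc_sd: float
    decision_trace: pd.DataFrame


# --- synthetic-data specs -------------------------------------------------

@dataclass
class IonBathSpec:
    """Electrolyte bath: bulk NaCl concentration, temperature, permittivity."""

    bulk_concentration: float = 0.6  # mol L^-1 (MD bath)
    temperature: float = 298.15  # K
    relative_permittivity: float = 78.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.bulk_concentration > 0:
            raise ValueError("bulk_concentration must be > 0")
        if not self.temperature > 0:
            raise ValueError("temperature must be > 0")
        if not self.relative_permittivity > 1:
            raise ValueError("relative_permittivity must be > 1")


#: 22-mer probe/target sequence used in the adsorption simulations
PROBE_SEQUENCE = "AACCACACAACCTACTACCTCA"

DNA_GEOMETRIES = ("flat", "concave", "convex", "across", "trench_bottom")


@dataclass
class DnaPlacement:
    """Backbone charge track of a single-stranded DNA along the surface."""

    sequence: str = PROBE_SEQUENCE
    geometry: str = "flat"
    charges_per_base: int = 1
    standoff: float = 0.35  # nm, π-stacking gap to the surface
    rise_per_base: float = 0.7  # nm along the track

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("sequence must be nonempty")
        bad = set(self.sequence.upper()) - set("ACGT")
        if bad:
            raise ValueError(f"sequence contains non-ACGT symbols: {sorted(bad)}")
        if self.geometry not in DNA_GEOMETRIES:
            raise ValueError(f"unknown geometry {self.geometry!r}")

    @property
    def n_sites(self) -> int:
        return len(self.sequence) * self.charges_per_base


@dataclass
class SipsParams:
    """Ground-truth Sips isotherm parameters for the dose generator.

    Defaults reproduce the reported crumpled-device response: a total
    saturation shift of ~180 mV, ~12 mV at 20 aM and a-few-mV signals at
    2 aM that sit inside the negative-control band.
    """

    dv_max: float = 180.0  # mV
    affinity_K: float = 3e13  # L mol^-1
    heterogeneity_a: float = 0.35
    noise_sd: float = 3.0  # mV
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.dv_max > 0:
            raise ValueError("dv_max must be > 0")
        if not self.affinity_K > 0:
            raise ValueError("affinity_K must be > 0")
        if not 0 < self.heterogeneity_a <= 2:
            raise ValueError("heterogeneity_a must be in (0, 2]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class BandgapMixture:
    """Background/hot-spot bandgap mixture of the deformed channel."""

    eg_background: float = 0.4224  # eV, crumpled graphene without DNA
    eg_hotspot: float = 1.7641  # eV, crumpled graphene with base A
    area_fraction_f: float = 0.0
    mobility_exponent: float = -1.5  # fixed µ ∝ E_g^(−3/2)

    def __post_init__(self) -> None:
        if not 0 <= self.area_fraction_f <= 1:
            raise ValueError("area_fraction_f must be in [0, 1]")
        if self.eg_background < 0 or self.eg_hotspot < 0:
            raise ValueError("bandgaps must be >= 0")
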