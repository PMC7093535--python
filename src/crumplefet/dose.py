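"""Sips isotherm dose–response modelling, limit of detection and molecule
counts.

``SipsModel`` / ``SipsResults`` follow the model-object convention of
statistical packages: the model is built from a :class:`DoseResponse`
table, ``fit()`` returns a results object carrying estimates, standard
errors, covariance and a ``summary()`` table, and prediction/plotting
hang off the results.

The isotherm is the Sips (Langmuir–Freundlich) binding model

    |ΔV|(C) = ΔV_max (K C)^a / (1 + (K C)^a)

with saturation shift ΔV_max (mV), affinity K (L mol⁻¹) and
heterogeneity exponent a ∈ (0, 2] (a = 1 recovers Langmuir).  Fitting is
performed against log₁₀-spaced concentrations (the measured doses span
~12 decades) with the affinity parameterised as log₁₀K for conditioning.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Optional

import lmfit
import numpy as np
import pandas as pd

from .constants import CONSTANTS
from .datatypes import DoseResponse, LodEstimate
from .synthetic import sips_shift


class FitError(RuntimeError):
    """Nonlinear fit failed to converge from every start."""


@dataclass
class SipsResults:
    """Fitted Sips isotherm: estimates, uncertainties and diagnostics.

    ``params``/``bse`` are keyed by dv_max (mV), affinity_K (L mol⁻¹) and
    heterogeneity_a; ``cov`` is the covariance of the internal
    (dv_max, log10_K, a) parameterisation, and ``bse_internal`` its
    standard errors (affinity_K's error is delta-method derived).
    """

    params: dict
    bse: dict
    bse_internal: dict
    cov: Optional[np.ndarray]
    residual_sd: float
    converged: bool
    at_bound: bool
    nfev: int
    n_obs: int
    model: "SipsModel" = field(repr=False, default=None)

    @property
    def dv_max(self) -> float:
        return self.params["dv_max"]

    @property
    def affinity_K(self) -> float:
        return self.params["affinity_K"]

    @property
    def heterogeneity_a(self) -> float:
        return self.params["heterogeneity_a"]

    def predict(self, concentration) -> np.ndarray:
        """Noiseless isotherm at the fitted parameters, mV."""
        return sips_shift(concentration, self.dv_max, self.affinity_K,
                          self.heterogeneity_a)

    def summary(self) -> str:
        lines = [
            "Sips isotherm fit",
            "=" * 46,
            f"{'observations':<22}{self.n_obs}",
            f"{'converged':<22}{self.converged}",
            f"{'residual SD (mV)':<22}{self.residual_sd:.3f}",
            "-" * 46,
            f"{'parameter':<18}{'estimate':>14}{'std err':>14}",
        ]
        units = {"dv_max": "mV", "affinity_K": "L/mol", "heterogeneity_a": ""}
        for name in ("dv_max", "affinity_K", "heterogeneity_a"):
            se = self.bse.get(name)
            se_s = f"{se:>14.4g}" if se is not None and np.isfinite(se) else f"{'--':>14}"
            lines.append(f"{name:<18}{self.params[name]:>14.6g}{se_s}  {units[name]}")
        if self.at_bound:
            lines.append("note: heterogeneity_a pinned at a bound")
        lines.append("=" * 46)
        return "\n".join(lines)

    def plot(self, ax=None):
        """Data and fitted isotherm on a log-concentration axis."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        pos = self.model.data.positive()
        ax.semilogx(pos["concentration"], pos["shift_mV"].abs(), "o",
                    label="measured")
        grid = np.geomspace(pos["concentration"].min() / 10,
                            pos["concentration"].max() * 10, 200)
        ax.semilogx(grid, self.predict(grid), "-", label="Sips fit")
        ax.set_xlabel("concentration (M)")
        ax.set_ylabel("|Dirac shift| (mV)")
        ax.legend()
        return ax


class SipsModel:
    """Sips dose–response model over a :class:`DoseResponse` table.

    Parameters
    ----------
    data : DoseResponse
        Needs ≥ 3 distinct positive concentrations.  Shifts enter as
        absolute values.
    weights : {"none", "relative"}
        Residual weighting.  "none" (default) is ordinary least squares,
        appropriate for additive instrument noise; "relative" divides the
        residuals by max(|model|, rel_floor).
    rel_floor : float
        Floor (mV) for relative weighting.
    """

    def __init__(self, data: DoseResponse, weights: str = "none",
                 rel_floor: float = 1.0):
        if weights not in ("none", "relative"):
            raise ValueError("weights must be 'none' or 'relative'")
        pos = data.positive()
        if pos["concentration"].nunique() < 3:
            raise ValueError("Sips fit needs >= 3 distinct positive concentrations")
        self.data = data
        self.weights = weights
        self.rel_floor = rel_floor
        self.conc = pos["concentration"].to_numpy(dtype=float)
        self.y = np.abs(pos["shift_mV"].to_numpy(dtype=float))

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, **kwargs) -> "SipsModel":
        """Build from a raw DataFrame with the DoseResponse columns."""
        return cls(DoseResponse(frame), **kwargs)

    # -- internals --------------------------------------------------------
    def _residual(self, params: lmfit.Parameters) -> np.ndarray:
        dv = params["dv_max"].value
        k = 10.0 ** params["log10_K"].value
        a = params["a"].value
        model = sips_shift(self.conc, dv, k, a)
        res = self.y - model
        if self.weights == "relative":
            res = res / np.maximum(np.abs(model), self.rel_floor)
        return res

    def _starts(self, n_starts: int) -> list:
        log_c = np.log10(self.conc)
        k_grid = np.linspace(-log_c.max() - 1.0, -log_c.min() + 1.0,
                             max(n_starts, 2))
        starts = []
        for k0 in k_grid:
            for a0 in (0.3, 1.0):
                starts.append((1.2 * self.y.max(), k0, a0))
        return starts

    def fit(self, n_starts: int = 5) -> SipsResults:
        """Multi-start nonlinear least squares; returns :class:`SipsResults`."""
        best = None
        for dv0, k0, a0 in self._starts(n_starts):
            params = lmfit.Parameters()
            params.add("dv_max", value=dv0, min=1e-9)
            params.add("log10_K", value=k0, min=-5.0, max=40.0)
            params.add("a", value=a0, min=1e-3, max=2.0)
            try:
                out = lmfit.minimize(self._residual, params, method="leastsq")
            except Exception:
                continue
            if best is None or out.chisqr < best.chisqr:
                best = out
        if best is None or not np.isfinite(best.chisqr):
            raise FitError("Sips fit did not converge from any start")

        p = best.params
        dv, lk, a = p["dv_max"].value, p["log10_K"].value, p["a"].value
        k = 10.0 ** lk
        se = {name: p[name].stderr for name in ("dv_max", "log10_K", "a")}
        se_k = (np.log(10.0) * k * se["log10_K"]
                if se["log10_K"] is not None else None)
        at_bound = bool(np.isclose(a, 2.0) or np.isclose(a, 1e-3))
        dof = max(self.y.size - 3, 1)
        return SipsResults(
            params={"dv_max": dv, "affinity_K": k, "heterogeneity_a": a},
            bse={"dv_max": se["dv_max"], "affinity_K": se_k,
                 "heterogeneity_a": se["a"]},
            bse_internal={"dv_max": se["dv_max"], "log10_K": se["log10_K"],
                          "a": se["a"]},
            cov=getattr(best, "covar", None),
            residual_sd=float(np.sqrt(best.chisqr / dof)),
            converged=bool(best.success),
            at_bound=at_bound, nfev=int(best.nfev), n_obs=int(self.y.size),
            model=self)


def fit_sips(data: DoseResponse, **kwargs) -> SipsResults:
    """Functional wrapper: ``SipsModel(data).fit()``."""
    fit_kwargs = {k: kwargs.pop(k) for k in ("n_starts",) if k in kwargs}
    return SipsModel(data, **kwargs).fit(**fit_kwargs)


def estimate_lod(data: DoseResponse, k_sigma: float = 3.0) -> LodEstimate:
    """Limit of detection against the negative-control band.

    A concentration is detected when its mean |shift| exceeds
    nc_mean + k_sigma · nc_sd (|shift| statistics of the negative-control
    replicates).  The LOD is the lowest tested concentration that is
    detected *and* whose higher concentrations are all detected too —
    single-point excursions below a run of failures do not count, matching
    the practice of discounting signals that overlap the control band.
    """
    nc = data.negative_controls()
    if len(nc) < 2:
        raise ValueError("need >= 2 negative-control replicates")
    nc_abs = nc["shift_mV"].abs()
    nc_mean, nc_sd = float(nc_abs.mean()), float(nc_abs.std(ddof=1))
    threshold = nc_mean + k_sigma * nc_sd

    pos = data.positive()
    by_c = (pos.assign(abs_shift=pos["shift_mV"].abs())
            .groupby("concentration")["abs_shift"].mean().sort_index())
    passed = by_c > threshold
    trace = pd.DataFrame({"concentration": by_c.index,
                          "mean_abs_shift_mV": by_c.values,
                          "threshold_mV": threshold,
                          "detected": passed.values})

    lod = None
    # lowest concentration from which detection persists upward
    persistent = passed[::-1].cumprod()[::-1].astype(bool)
    if persistent.any():
        lod = float(persistent[persistent].index.min())
    return LodEstimate(lod_concentration=lod,
                       criterion=f"mean|shift| > nc_mean + {k_sigma:g}*nc_sd, "
                                 "persistent at all higher concentrations",
                       nc_mean=nc_mean, nc_sd=nc_sd, decision_trace=trace)


class MoleculeCount(NamedTuple):
    count: int
    exact: float


def molecules_from_concentration(concentration: float, volume: float) -> MoleculeCount:
    """Number of molecules in a sample: round(C · V · N_A).

    concentration in mol L⁻¹, volume in L; e.g. 20 aM in 50 µL is ≈600
    molecules and 600 zM in 50 µL is ≈18.
    """
    if concentration < 0 or volume <= 0:
        raise ValueError("concentration must be >= 0 and volume > 0")
    exact = concentration * volume * CONSTANTS.avogadro_NA
    return MoleculeCount(count=int(round(exact)), exact=exact)
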