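"""Model surfaces (flat, sinusoidal crumple, trench groove) and the
distance-from-surface coordinate.

The coordinate convention used throughout: the mean graphene plane is at
z = 0 and the electrolyte occupies z > 0 (the sinusoid dips to -amplitude,
the trench groove to -trench_radius).  ``surface_distance`` returns the
minimal Euclidean distance to the surface manifold, signed negative for
points below/inside the solid region.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

_GOLDEN = (np.sqrt(5.0) - 1.0) / 2.0


@dataclass
class SurfaceModel:
    """Geometry and charge state of the sensing surface.

    Parameters
    ----------
    kind : {"flat", "sinusoid", "trench"}
    wavelength, amplitude : float
        Crumple wavelength and amplitude in nm (sinusoid only).  Defaults
        are the 5.41 nm / 0.73 nm corrugation used for the crumpled-sheet
        simulations.
    trench_radius, trench_length : float
        Half-cylinder groove radius and axial length in nm.  Defaults model
        the 2.45 nm diameter, 8 nm long narrow trench.
    trench_x0 : float
        x position of the groove axis, nm.
    sigma : float
        Surface charge density, C m⁻² (negative for p-doped graphene in
        electrolyte).
    area_A : float, optional
        Wetted surface area in m²; computed from a box via
        :meth:`wetted_area` when needed.
    """

    kind: str
    wavelength: float = 5.41
    amplitude: float = 0.73
    trench_radius: float = 1.225
    trench_length: float = 8.0
    trench_x0: float = 0.0
    sigma: float = -0.02
    area_A: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind not in ("flat", "sinusoid", "trench"):
            raise ValueError(f"unknown surface kind {self.kind!r}")
        if self.kind == "sinusoid":
            if not self.wavelength > 0:
                raise ValueError("wavelength must be > 0")
            if self.amplitude < 0:
                raise ValueError("amplitude must be >= 0")
        if self.kind == "trench" and not self.trench_radius > 0:
            raise ValueError("trench_radius must be > 0")
        if self.area_A is not None and not self.area_A > 0:
            raise ValueError("area_A must be > 0")

    # -- geometry ---------------------------------------------------------
    def height(self, x: np.ndarray) -> np.ndarray:
        """Surface height z = s(x) in nm (uniform along y)."""
        x = np.asarray(x, dtype=float)
        if self.kind == "flat" or (self.kind == "sinusoid" and self.amplitude == 0):
            return np.zeros_like(x)
        if self.kind == "sinusoid":
            return self.amplitude * np.cos(2.0 * np.pi * x / self.wavelength)
        dx = np.abs(x - self.trench_x0)
        h = np.zeros_like(x)
        inside = dx < self.trench_radius
        h[inside] = -np.sqrt(self.trench_radius**2 - dx[inside] ** 2)
        return h

    def z_min(self) -> float:
        """Lowest surface point in nm."""
        if self.kind == "sinusoid":
            return -self.amplitude
        if self.kind == "trench":
            return -self.trench_radius
        return 0.0

    def wetted_area(self, lx: float, ly: float) -> float:
        """Actual surface area (m²) of one box footprint lx × ly nm²."""
        if self.kind == "flat" or (self.kind == "sinusoid" and self.amplitude == 0):
            return lx * ly * 1e-18
        if self.kind == "sinusoid":
            k = 2.0 * np.pi / self.wavelength
            x = np.linspace(0.0, self.wavelength, 4001)
            arc = np.trapezoid(np.sqrt(1.0 + (self.amplitude * k * np.sin(k * x)) ** 2), x)
            return (lx / self.wavelength) * arc * ly * 1e-18
        flat_part = max(lx - 2.0 * self.trench_radius, 0.0)
        groove = np.pi * self.trench_radius
        return (flat_part + groove) * ly * 1e-18


def _sinusoid_distance(px: np.ndarray, pz: np.ndarray, surface: SurfaceModel,
                       n_coarse: int = 129, n_refine: int = 40) -> tuple:
    """Unsigned min distance of (x, z) points to z = A cos(2πx/λ).

    Coarse grid search over ±0.75 λ around each point followed by a
    vectorised golden-section refinement of the bracketing interval.
    Returns (distance, x_star) with x_star the nearest surface x.
    """
    wl, amp = surface.wavelength, surface.amplitude
    offsets = np.linspace(-0.75 * wl, 0.75 * wl, n_coarse)

    def f(x):
        return (x - px) ** 2 + (amp * np.cos(2.0 * np.pi * x / wl) - pz) ** 2

    d2 = offsets[None, :] ** 2 + (
        amp * np.cos(2.0 * np.pi * (px[:, None] + offsets[None, :]) / wl) - pz[:, None]
    ) ** 2
    j = np.argmin(d2, axis=1)
    step = offsets[1] - offsets[0]
    a = px + offsets[j] - step
    b = px + offsets[j] + step
    for _ in range(n_refine):
        c = b - _GOLDEN * (b - a)
        d = a + _GOLDEN * (b - a)
        take_left = f(c) < f(d)
        b = np.where(take_left, d, b)
        a = np.where(take_left, a, c)
    x_star = 0.5 * (a + b)
    return np.sqrt(f(x_star)), x_star


def _trench_distance(px: np.ndarray, pz: np.ndarray, surface: SurfaceModel) -> np.ndarray:
    """Unsigned min distance to the flat-plane + half-cylinder-groove surface."""
    R = surface.trench_radius
    dx = np.abs(px - surface.trench_x0)
    # flat part {|x - x0| >= R, z = 0}
    d_flat = np.where(dx >= R, np.abs(pz), np.hypot(R - dx, pz))
    # groove arc: lower half of the circle radius R centred on (x0, 0)
    r = np.hypot(dx, pz)
    d_arc = np.where(pz <= 0, np.abs(r - R), np.hypot(dx - R, pz))
    return np.minimum(d_flat, d_arc)


def surface_distance(points: np.ndarray, surface: SurfaceModel,
                     chunk: int = 20000) -> np.ndarray:
    """Signed distance from points to the surface manifold, in nm.

    Parameters
    ----------
    points : (N, 3) or (3,) array
        Positions in nm.  The surface is uniform along y, so only x and z
        enter.
    surface : SurfaceModel
    chunk : int
        Points per vectorised block (memory control for the sinusoid
        search).

    Returns
    -------
    ndarray or float
        Minimal Euclidean distance to the surface; negative for points in
        the solid region below the sheet.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    px, pz = pts[:, 0], pts[:, 2]

    if surface.kind == "flat" or (surface.kind == "sinusoid" and surface.amplitude == 0):
        out = pz.copy()
    elif surface.kind == "sinusoid":
        out = np.empty_like(pz)
        for i in range(0, len(px), chunk):
            sl = slice(i, i + chunk)
            out[sl], _ = _sinusoid_distance(px[sl], pz[sl], surface)
        below = pz < surface.height(px)
        out[below] *= -1.0
    else:
        out = _trench_distance(px, pz, surface)
        dx = np.abs(px - surface.trench_x0)
        solid = (pz < 0) & (np.hypot(dx, pz) >= surface.trench_radius)
        out[solid] *= -1.0

    if np.asarray(points).ndim == 1:
        return float(out[0])
    return out


def surface_geometry(points: np.ndarray, surface: SurfaceModel,
                     chunk: int = 20000) -> tuple:
    """Signed distance plus concave curvature κ⁺ at the nearest point.

    κ⁺ (nm⁻¹) is the surface curvature toward the fluid where the surface
    is concave (valley bottoms, trench groove) and 0 where it is flat or
    convex.  Used by the synthetic sampler's confinement penalty.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    px, pz = pts[:, 0], pts[:, 2]

    if surface.kind == "flat" or (surface.kind == "sinusoid" and surface.amplitude == 0):
        return pz.copy(), np.zeros_like(pz)

    if surface.kind == "sinusoid":
        d = np.empty_like(pz)
        x_star = np.empty_like(pz)
        for i in range(0, len(px), chunk):
            sl = slice(i, i + chunk)
            d[sl], x_star[sl] = _sinusoid_distance(px[sl], pz[sl], surface)
        below = pz < surface.height(px)
        d[below] *= -1.0
        k = 2.0 * np.pi / surface.wavelength
        s1 = -surface.amplitude * k * np.sin(k * x_star)
        s2 = -surface.amplitude * k * k * np.cos(k * x_star)
        kappa = s2 / (1.0 + s1**2) ** 1.5  # >0 where concave toward fluid
        return d, np.maximum(kappa, 0.0)

    d = _trench_distance(px, pz, surface)
    dx = np.abs(px - surface.trench_x0)
    r = np.hypot(dx, pz)
    solid = (pz < 0) & (r >= surface.trench_radius)
    d = np.where(solid, -d, d)
    in_groove = (pz <= 0) & (r < surface.trench_radius)
    kappa = np.where(in_groove, 1.0 / surface.trench_radius, 0.0)
    return d, kappa
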