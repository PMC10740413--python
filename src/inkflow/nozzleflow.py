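"""Quasi-1D laminar flow of a power-law ink through a syringe nozzle.

The extrusion channel (barrel front end + conical transition + needle) is a
slender axisymmetric duct, so steady, incompressible, no-slip flow of a
power-law fluid is modelled with the lubrication approximation: each axial
station is treated as locally fully developed pipe flow, and the
generalized Hagen-Poiseuille pressure gradient

    dP/dz = (2K / R) * ( (3n+1)/n * Q / (pi R^3) )**n

is integrated along the axis.  Cylindrical segments use the closed form
directly; conical segments (linear taper) are integrated with composite
Simpson quadrature.  Given an applied pressure, the flow rate is found by
bracketed root finding on log Q.  The exit velocity profile is the fully
developed power-law profile

    u(r) = (G / 2K)**(1/n) * n/(n+1) * (R**(1+1/n) - r**(1+1/n))

with G the exit-segment gradient.  Entrance/exit losses and extrudate
swell are not modelled.

Interface units: lengths mm, pressure kPa, flow rate uL/s (1 uL/s =
1 mm^3/s); SI internally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_simpson, simpson
from scipy.optimize import brentq

__all__ = [
    "NozzleSegment",
    "NozzleGeometry",
    "FlowSolution",
    "default_geometry",
    "local_pressure_gradient",
    "pressure_drop",
    "solve_flow_rate",
    "flow_rate_from_profile",
    "filament_diameter",
    "FlowSolverError",
]

# quadrature resolution (fixed-panel composite Simpson)
AXIAL_PANELS = 2048
RADIAL_PANELS = 1024

_UL_S = 1e-9     # uL/s  -> m^3/s
_MM = 1e-3       # mm    -> m
_KPA = 1e3       # kPa   -> Pa


class FlowSolverError(RuntimeError):
    """Root bracketing for the flow rate failed; carries diagnostics."""


@dataclass(frozen=True)
class NozzleSegment:
    """One axial segment: cylindrical (equal radii) or conical (linear taper)."""

    length_mm: float
    r_in_mm: float
    r_out_mm: float

    def __post_init__(self) -> None:
        for name, v in (("length_mm", self.length_mm), ("r_in_mm", self.r_in_mm),
                        ("r_out_mm", self.r_out_mm)):
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be finite and > 0, got {v}")

    @property
    def is_cylindrical(self) -> bool:
        return self.r_in_mm == self.r_out_mm


@dataclass(frozen=True)
class NozzleGeometry:
    """Ordered axial segments from barrel inlet to tip exit.

    Radii must be continuous across joints; the last segment's outlet
    radius is the tip inner radius.
    """

    segments: tuple[NozzleSegment, ...]

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("geometry needs at least one segment")
        object.__setattr__(self, "segments", tuple(self.segments))
        for a, b in zip(self.segments, self.segments[1:]):
            if not np.isclose(a.r_out_mm, b.r_in_mm, rtol=1e-12, atol=0.0):
                raise ValueError(
                    f"radius discontinuity at joint: {a.r_out_mm} != {b.r_in_mm} mm")

    @property
    def exit_radius_mm(self) -> float:
        return self.segments[-1].r_out_mm

    @property
    def total_length_mm(self) -> float:
        return sum(s.length_mm for s in self.segments)


def default_geometry() -> NozzleGeometry:
    """3 mL syringe front end with a 25 G needle tip (ID 0.25 mm).

    Barrel R 4.8 mm x 10 mm, conical transition 4.8 -> 0.125 mm over
    20 mm, needle cannula R 0.125 mm x 12.7 mm (half-inch 25 G).  The
    needle length dominates the pressure drop and puts the solved flow
    rates for mid-range inks at typical extrusion pressures inside the
    0-4 uL/s window reported for printable gelatin-alginate inks.
    """
    return NozzleGeometry(segments=(
        NozzleSegment(10.0, 4.8, 4.8),
        NozzleSegment(20.0, 4.8, 0.125),
        NozzleSegment(12.7, 0.125, 0.125),
    ))


@dataclass(frozen=True)
class FlowSolution:
    """Solved nozzle flow: rate, pressure profile and exit velocity profile."""

    q_ul_s: float
    pressure_kpa: float
    z_mm: np.ndarray          # axial stations, 0 at inlet
    p_kpa: np.ndarray         # pressure above ambient at each station
    r_mm: np.ndarray          # radial grid at the exit, 0..R
    u_mm_s: np.ndarray        # axial velocity at the exit
    wall_shear_rate_per_s: float


# ---------------------------------------------------------------------------
# Core relations
# ---------------------------------------------------------------------------

def local_pressure_gradient(params, q_ul_s: float, radius_mm: float) -> float:
    """Generalized Hagen-Poiseuille pressure gradient, Pa/m.

    For fully developed power-law pipe flow at flow rate Q through local
    radius R:  dP/dz = (2K/R) * ((3n+1)/n * Q/(pi R^3))**n.  Reduces to
    the Newtonian 8*mu*Q/(pi R^4) at n = 1, K = mu.
    """
    if q_ul_s <= 0:
        raise ValueError(f"flow rate must be > 0, got {q_ul_s}")
    if np.any(np.asarray(radius_mm) <= 0):
        raise ValueError("radius must be > 0")
    Q = q_ul_s * _UL_S
    R = np.asarray(radius_mm, dtype=float) * _MM
    g = (2.0 * params.K / R) * ((3.0 * params.n + 1.0) / params.n
                                * Q / (np.pi * R ** 3)) ** params.n
    return float(g) if np.isscalar(radius_mm) else g


def _segment_drop(params, q_ul_s: float, seg: NozzleSegment) -> float:
    """Total drop in Pa across one segment."""
    if seg.is_cylindrical:
        return local_pressure_gradient(params, q_ul_s, seg.r_in_mm) * seg.length_mm * _MM
    z = np.linspace(0.0, seg.length_mm, AXIAL_PANELS + 1)
    R = seg.r_in_mm + (seg.r_out_mm - seg.r_in_mm) * z / seg.length_mm
    return float(simpson(local_pressure_gradient(params, q_ul_s, R), x=z * _MM))


def _segment_profile(params, q_ul_s: float, seg: NozzleSegment,
                     ) -> tuple[np.ndarray, np.ndarray]:
    """(z_mm grid, cumulative drop in Pa along the segment)."""
    if seg.is_cylindrical:
        z = np.array([0.0, seg.length_mm])
        g = local_pressure_gradient(params, q_ul_s, seg.r_in_mm)
        return z, np.array([0.0, g * seg.length_mm * _MM])
    z = np.linspace(0.0, seg.length_mm, AXIAL_PANELS + 1)
    R = seg.r_in_mm + (seg.r_out_mm - seg.r_in_mm) * z / seg.length_mm
    g = local_pressure_gradient(params, q_ul_s, R)
    drop = cumulative_simpson(g, x=z * _MM, initial=0.0)
    return z, drop


def pressure_drop(params, geometry: NozzleGeometry, q_ul_s: float,
                  return_profile: bool = False):
    """Total pressure drop in kPa for flow rate Q (uL/s) through the nozzle.

    Cylindrical segments use the closed-form gradient; conical segments
    integrate the lubrication gradient along the linear taper with
    composite Simpson quadrature.  Strictly increasing in Q.  With
    ``return_profile=True`` also returns (z_mm, drop_kpa) axial arrays.
    """
    if q_ul_s <= 0:
        raise ValueError(f"flow rate must be > 0, got {q_ul_s}")
    if not return_profile:
        return sum(_segment_drop(params, q_ul_s, s) for s in geometry.segments) / _KPA
    z_all, d_all = [0.0], [0.0]
    z0, acc = 0.0, 0.0
    for seg in geometry.segments:
        z, drop = _segment_profile(params, q_ul_s, seg)
        z_all.extend((z0 + z[1:]).tolist())
        d_all.extend((acc + drop[1:]).tolist())
        z0 += seg.length_mm
        acc += drop[-1]
    return acc / _KPA, np.asarray(z_all), np.asarray(d_all) / _KPA


def _exit_profile(params, geometry: NozzleGeometry, q_ul_s: float,
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Fully developed power-law velocity profile at the exit radius."""
    n, K = params.n, params.K
    R = geometry.exit_radius_mm * _MM
    G = local_pressure_gradient(params, q_ul_s, geometry.exit_radius_mm)
    r = np.linspace(0.0, R, RADIAL_PANELS + 1)
    u = (G / (2.0 * K)) ** (1.0 / n) * n / (n + 1.0) * (
        R ** (1.0 + 1.0 / n) - r ** (1.0 + 1.0 / n))
    return r / _MM, u / _MM  # mm, mm/s


def solve_flow_rate(params, geometry: NozzleGeometry,
                    pressure_kpa: float) -> FlowSolution:
    """Invert the pressure-drop relation: flow rate for an applied pressure.

    Brackets log Q starting from [1e-6, 1e3] uL/s, doubling the bracket up
    to a cap when the pressure lies outside, then solves with Brent's
    method on log Q to 1e-10 relative tolerance.  Returns the full
    solution: axial pressure profile (monotone non-increasing along the
    flow), exit velocity profile and exit wall shear rate.
    """
    if pressure_kpa <= 0:
        raise ValueError(f"pressure must be > 0, got {pressure_kpa}")
    target = np.log(pressure_kpa)

    def f(logq: float) -> float:
        return np.log(pressure_drop(params, geometry, np.exp(logq))) - target

    lo, hi = np.log(1e-6), np.log(1e3)
    for _ in range(60):
        flo, fhi = f(lo), f(hi)
        if flo <= 0.0 <= fhi:
            break
        if flo > 0.0:
            lo -= np.log(2.0)
        if fhi < 0.0:
            hi += np.log(2.0)
    else:
        raise FlowSolverError(
            f"could not bracket Q for P={pressure_kpa} kPa, n={params.n}, "
            f"K={params.K}; last bracket [{np.exp(lo)}, {np.exp(hi)}] uL/s")
    logq = brentq(f, lo, hi, rtol=1e-12, xtol=1e-14)
    q = float(np.exp(logq))

    _, z_mm, drop_kpa = pressure_drop(params, geometry, q, return_profile=True)
    r_mm, u_mm_s = _exit_profile(params, geometry, q)
    R = geometry.exit_radius_mm * _MM
    wall_rate = (3.0 * params.n + 1.0) / params.n * (q * _UL_S) / (np.pi * R ** 3)
    return FlowSolution(
        q_ul_s=q, pressure_kpa=pressure_kpa,
        z_mm=z_mm, p_kpa=pressure_kpa - drop_kpa,
        r_mm=r_mm, u_mm_s=u_mm_s,
        wall_shear_rate_per_s=float(wall_rate),
    )


def flow_rate_from_profile(r_mm, u_mm_s, rtol_wall: float = 1e-6) -> float:
    """Flow rate uL/s from a radial velocity profile: Q = 2*pi * int u r dr.

    Composite quadrature on the supplied grid; the outermost sample is
    taken as the wall and must be ~0 (no slip) relative to the peak.
    """
    r = np.asarray(r_mm, dtype=float)
    u = np.asarray(u_mm_s, dtype=float)
    if r.shape != u.shape or r.ndim != 1 or r.size < 3:
        raise ValueError("need matching 1-D r and u arrays with >= 3 points")
    if abs(u[-1]) > rtol_wall * max(abs(u).max(), 1e-300):
        raise ValueError("velocity at the wall is not ~0 (no-slip violated)")
    return float(2.0 * np.pi * simpson(u * r, x=r))  # mm^3/s == uL/s


def filament_diameter(q_ul_s: float, v_mm_s: float) -> float:
    """Deposited filament diameter d = 2*sqrt(Q / (pi v)) in mm.

    Mass conservation for a filament stretched into a uniform cylinder at
    print speed v: Q (uL/s = mm^3/s) deposited over v mm of path per
    second gives cross-section Q/v = pi (d/2)^2.
    """
    if q_ul_s <= 0 or v_mm_s <= 0:
        raise ValueError("flow rate and print speed must be > 0")
    return 2.0 * np.sqrt(q_ul_s / (np.pi * v_mm_s))
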