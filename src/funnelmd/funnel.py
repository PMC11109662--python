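"""Funnel-shaped restraint: geometry, wall potential, and axial projection.

The restraint is the cone-plus-cylinder construction of funnel metadynamics:
a cone of half-aperture ``alpha`` opens from the binding pocket along the
egress axis and merges into a cylinder of radius ``r_cyl`` at the axial
coordinate ``z_cc``.  Positions whose radial distance from the axis exceeds
the local funnel radius feel a one-sided harmonic wall of stiffness
``k_wall``; everything inside is untouched.  The cylindrical section gives
the unbound ligand a flat-bottomed tube of known cross-section
``pi * r_cyl**2``, which is what makes the standard-state correction of the
binding constant analytic (see :mod:`funnelmd.fes`).

The axis is user input (in the original application it follows the
H3-H7-H11 egress channel identified by RAMD); no automatic placement from a
protein structure is attempted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FunnelGeometry",
    "funnel_radius",
    "wall_energy",
    "wall_force",
    "axial_decompose",
]


@dataclass(frozen=True)
class FunnelGeometry:
    """Cone + cylinder restraint region.

    Parameters
    ----------
    origin : (3,) array, nm
        Anchor point of the funnel axis inside the pocket.
    axis : (3,) array
        Unit vector pointing along the egress direction.
    z_cc : float, nm
        Axial distance at which the cone merges into the cylinder.
    r_cyl : float, nm
        Cylinder radius (also the minimum funnel radius).
    alpha : float, rad
        Cone half-aperture measured from the axis; 0 < alpha < pi/2.
    k_wall : float, kJ mol^-1 nm^-2
        One-sided harmonic wall stiffness.  The default is stiff enough
        that a toy particle at 300 K leaves the funnel in well under 0.1%
        of steps.
    """

    origin: np.ndarray
    axis: np.ndarray
    z_cc: float
    r_cyl: float
    alpha: float
    k_wall: float = 10000.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float))
        object.__setattr__(self, "axis", np.asarray(self.axis, dtype=float))
        if self.origin.shape != (3,) or self.axis.shape != (3,):
            raise ValueError("origin and axis must be 3-vectors")
        if abs(np.linalg.norm(self.axis) - 1.0) > 1e-9:
            raise ValueError("axis must be a unit vector (|axis| = 1 within 1e-9); "
                             "normalize on load")
        if not self.z_cc > 0:
            raise ValueError("z_cc must be positive")
        if not self.r_cyl > 0:
            raise ValueError("r_cyl must be positive")
        if not 0 < self.alpha < math.pi / 2:
            raise ValueError("alpha must lie in (0, pi/2)")
        if not self.k_wall > 0:
            raise ValueError("k_wall must be positive")

    @property
    def tan_alpha(self) -> float:
        return math.tan(self.alpha)


def funnel_radius(z, geom: FunnelGeometry):
    """Funnel radius at axial coordinate ``z`` (nm).

    Returns ``r_cyl`` for ``z >= z_cc`` and
    ``r_cyl + (z_cc - z) * tan(alpha)`` for ``z < z_cc``; continuous at the
    switch and strictly decreasing on the cone side.  Total on real ``z``.
    """
    z = np.asarray(z, dtype=float)
    r = geom.r_cyl + np.where(z < geom.z_cc, (geom.z_cc - z) * geom.tan_alpha, 0.0)
    return float(r) if r.ndim == 0 else r


def axial_decompose(pos, geom: FunnelGeometry):
    """Project a position onto the funnel axis.

    Returns ``(z, rho)`` with ``z = (pos - origin) . axis`` and ``rho`` the
    perpendicular distance from the axis.  The original position is
    recoverable as ``origin + z*axis + rho*e_rho``.
    """
    d = np.asarray(pos, dtype=float) - geom.origin
    z = float(np.dot(d, geom.axis))
    radial = d - z * geom.axis
    rho = float(np.linalg.norm(radial))
    return z, rho


def wall_energy(pos, geom: FunnelGeometry) -> float:
    """One-sided harmonic wall energy, kJ/mol.

    Zero inside the funnel (rho <= funnel_radius(z)), otherwise
    ``k_wall/2 * (rho - funnel_radius(z))**2``.  Continuous and once
    differentiable across the wall.
    """
    z, rho = axial_decompose(pos, geom)
    excess = rho - funnel_radius(z, geom)
    if excess <= 0.0:
        return 0.0
    return 0.5 * geom.k_wall * excess * excess


def wall_force(pos, geom: FunnelGeometry) -> np.ndarray:
    """Cartesian force (kJ mol^-1 nm^-1) exerted by the funnel wall.

    The wall energy depends on position through both the radial excess and,
    on the cone side, the z-dependence of the funnel radius; both terms are
    included so that the force is the exact negative gradient.
    """
    pos = np.asarray(pos, dtype=float)
    d = pos - geom.origin
    z = float(np.dot(d, geom.axis))
    radial = d - z * geom.axis
    rho = float(np.linalg.norm(radial))
    excess = rho - funnel_radius(z, geom)
    if excess <= 0.0 or rho == 0.0:
        return np.zeros(3)
    e_rho = radial / rho
    f = -geom.k_wall * excess * e_rho
    if z < geom.z_cc:
        # dR/dz = -tan(alpha) on the cone side: dE/dz = k*excess*tan(alpha)
        f = f - geom.k_wall * excess * geom.tan_alpha * geom.axis
    return f
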