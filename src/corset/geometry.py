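"""Axisymmetric mid-surface geometry for a coupled two-membrane system.

The outer membrane (OMM) and the inner boundary membrane (IBM) run parallel
at a fixed separation ``d``; the whole system is represented by the
mid-surface half-way between them.  A closed axisymmetric mid-surface is
discretized as a profile curve parametrized by arclength ``s`` and tilt
angle ``psi`` (angle between the profile tangent and the plane normal to
the symmetry axis), from which the radius ``r(s)`` and axial coordinate
``z(s)`` follow by quadrature:

    dr/ds = cos(psi),   dz/ds = sin(psi).

The local shape is summarized by the total (twice-mean) curvature

    J = c_p1 + c_p2 = dpsi/ds + sin(psi)/r,

with the pole limit J -> 2*dpsi/ds as r -> 0.  The Gaussian curvature is
neglected throughout: the model operates in the small-curvature regime
|J|*d << 1, where it contributes at higher order.

All lengths are in nm, areas in nm^2, volumes in nm^3.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid, simpson

from .errors import (
    DegenerateShapeError,
    InvalidParameterError,
    InvalidShapeError,
    ModelValidityError,
)

#: radius below which a node is treated as lying on the symmetry axis (nm)
POLE_TOL = 1e-9


@dataclass
class AxisymmetricShape:
    """Discretized profile of an axisymmetric surface of revolution.

    Parameters
    ----------
    s : ndarray
        Arclength grid in nm, strictly increasing, ``s[0] == 0``.
    psi : ndarray
        Tilt angle of the profile tangent in radians.
    r : ndarray
        Distance from the symmetry axis in nm, non-negative.
    z : ndarray
        Axial coordinate in nm.
    closed : bool
        Whether both profile ends lie on the symmetry axis (poles).
    """

    s: np.ndarray
    psi: np.ndarray
    r: np.ndarray
    z: np.ndarray
    closed: bool = True

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=float)
        self.psi = np.asarray(self.psi, dtype=float)
        self.r = np.asarray(self.r, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        n = self.s.size
        if not (self.psi.size == self.r.size == self.z.size == n) or n < 5:
            raise InvalidShapeError("profile arrays must share a length >= 5")
        if self.s[0] != 0.0 or np.any(np.diff(self.s) <= 0):
            raise InvalidShapeError("arclength must start at 0 and increase strictly")
        if np.any(self.r < -POLE_TOL):
            raise InvalidShapeError("radius must be non-negative everywhere")

    @property
    def n_nodes(self) -> int:
        return self.s.size

    @classmethod
    def from_tilt_profile(
        cls, s: np.ndarray, psi: np.ndarray, closed: bool = True
    ) -> "AxisymmetricShape":
        """Build a shape from (s, psi) by integrating the profile ODEs."""
        s = np.asarray(s, dtype=float)
        psi = np.asarray(psi, dtype=float)
        r = cumulative_trapezoid(np.cos(psi), s, initial=0.0)
        z = cumulative_trapezoid(np.sin(psi), s, initial=0.0)
        if closed:
            # snap the numerically-closed far pole exactly onto the axis
            r = r - r[-1] * s / s[-1]
            r[np.abs(r) < POLE_TOL] = 0.0
        return cls(s=s, psi=psi, r=r, z=z, closed=closed)

    def require_closed(self) -> None:
        if not self.closed:
            raise InvalidShapeError("operation requires a closed profile")
        if abs(self.r[0]) > POLE_TOL * max(1.0, self.s[-1]) or abs(
            self.r[-1]
        ) > 1e-6 * self.s[-1]:
            raise InvalidShapeError("closed profile must start and end on the axis")
        interior = self.r[1:-1]
        if np.any(interior <= POLE_TOL):
            idx = int(np.argmax(interior <= POLE_TOL)) + 1
            raise DegenerateShapeError(
                f"radius vanishes at interior node {idx} (s={self.s[idx]:.3g} nm)"
            )

    def mean_curvature(self) -> np.ndarray:
        """Total curvature J(s) = dpsi/ds + sin(psi)/r, nm^-1.

        At poles the azimuthal term sin(psi)/r tends to dpsi/ds
        (L'Hopital), giving the limit J -> 2*dpsi/ds.
        """
        dpsi = np.gradient(self.psi, self.s)
        J = np.empty_like(self.r)
        on_axis = self.r <= POLE_TOL * max(1.0, self.s[-1])
        with np.errstate(divide="ignore", invalid="ignore"):
            J[~on_axis] = dpsi[~on_axis] + np.sin(self.psi[~on_axis]) / self.r[~on_axis]
        J[on_axis] = 2.0 * dpsi[on_axis]
        return J


@dataclass
class MembraneSystem:
    """Areas of the coupled outer/inner membranes around one mid-surface.

    ``area_out``/``area_in`` follow from the parallel-surface relations
    A_out = A + (d/2)*M and A_in = A - (d/2)*M, where M is the integrated
    total curvature of the mid-surface; hence ΔA = d*M = d*<J>*A.
    """

    mid_area: float
    d: float
    area_out: float
    area_in: float
    area_diff: float = field(init=False)

    def __post_init__(self) -> None:
        self.area_diff = self.area_out - self.area_in

    @property
    def dA_over_A(self) -> float:
        return self.area_diff / self.mid_area


def make_sphere(mid_area: float, n_nodes: int = 200) -> AxisymmetricShape:
    """Closed sphere whose surface area equals ``mid_area`` (nm^2).

    The profile is sampled uniformly in arclength; the radius follows
    R = sqrt(mid_area / 4π).
    """
    if not mid_area > 0:
        raise InvalidParameterError(f"mid_area must be positive, got {mid_area}")
    R = float(np.sqrt(mid_area / (4.0 * np.pi)))
    s = np.linspace(0.0, np.pi * R, n_nodes)
    psi = s / R
    r = R * np.sin(psi)
    z = R * (1.0 - np.cos(psi))
    r[0] = r[-1] = 0.0
    return AxisymmetricShape(s=s, psi=psi, r=r, z=z, closed=True)


def make_spheroid(a: float, b: float, n_nodes: int = 400) -> AxisymmetricShape:
    """Spheroid with polar semi-axis ``a`` and equatorial semi-axis ``b`` (nm).

    Sampled uniformly in the elliptic parameter; prolate for a > b.
    """
    if not (a > 0 and b > 0):
        raise InvalidParameterError("semi-axes must be positive")
    theta = np.linspace(0.0, np.pi, n_nodes)
    r = b * np.sin(theta)
    z = a * (1.0 - np.cos(theta))
    dr = b * np.cos(theta)
    dz = a * np.sin(theta)
    psi = np.arctan2(dz, dr)
    ds = np.sqrt(dr**2 + dz**2)
    s = cumulative_trapezoid(ds, theta, initial=0.0)
    r[0] = r[-1] = 0.0
    return AxisymmetricShape(s=s, psi=psi, r=r, z=z, closed=True)


def surface_area(shape: AxisymmetricShape) -> float:
    """Area ∮dA = ∫ 2π r ds of the surface of revolution, nm^2."""
    return float(simpson(2.0 * np.pi * shape.r, x=shape.s))


def enclosed_volume(shape: AxisymmetricShape) -> float:
    """Volume ∫ π r² sin(psi) ds enclosed by a closed profile, nm^3."""
    return float(simpson(np.pi * shape.r**2 * np.sin(shape.psi), x=shape.s))


def integrated_mean_curvature(shape: AxisymmetricShape) -> float:
    """M = ∮ J dA = ∫ 2π (r·dpsi/ds + sin psi) ds, nm."""
    dpsi = np.gradient(shape.psi, shape.s)
    integrand = 2.0 * np.pi * (shape.r * dpsi + np.sin(shape.psi))
    return float(simpson(integrand, x=shape.s))


def sphericity_3d(area: float, volume: float) -> float:
    """36π V²/A³ — unity for a sphere, decreasing with elongation."""
    return 36.0 * np.pi * volume**2 / area**3


def geometry_report(shape: AxisymmetricShape) -> dict:
    """Differential-geometric summary of a closed shape.

    Returns area (nm^2), volume (nm^3), the integrated total curvature
    ``M`` (nm), the curvature profile ``J`` (nm^-1) on the arclength grid,
    and the dimensionless sphericity 36π V²/A³.
    """
    shape.require_closed()
    A = surface_area(shape)
    V = enclosed_volume(shape)
    M = integrated_mean_curvature(shape)
    J = shape.mean_curvature()
    return {
        "area": A,
        "volume": V,
        "integrated_mean_curvature": M,
        "mean_curvature_profile": J,
        "sphericity_3d": sphericity_3d(A, V),
    }


def willmore_energy(shape: AxisymmetricShape) -> float:
    """∮ J² dA — scale-invariant; ≥ 16π for any closed surface."""
    J = shape.mean_curvature()
    return float(simpson(J**2 * 2.0 * np.pi * shape.r, x=shape.s))


def membrane_areas(shape: AxisymmetricShape, d: float) -> MembraneSystem:
    """Outer/inner membrane areas at separation ``d`` (nm) around the mid-surface.

    Valid only in the small-curvature regime max|J|*d < 1; violating nodes
    indicate membranes closer than the local radius of curvature, where the
    parallel-surface construction self-intersects.
    """
    if d < 0:
        raise InvalidParameterError("intermembrane distance d must be >= 0")
    shape.require_closed()
    J = shape.mean_curvature()
    Jd = np.abs(J) * d
    if np.any(Jd >= 1.0):
        idx = int(np.argmax(Jd))
        raise ModelValidityError(
            f"|J|*d = {Jd[idx]:.3f} >= 1 at node {idx} (s={shape.s[idx]:.3g} nm); "
            "small-curvature regime violated"
        )
    A = surface_area(shape)
    M = integrated_mean_curvature(shape)
    return MembraneSystem(
        mid_area=A,
        d=d,
        area_out=A + 0.5 * d * M,
        area_in=A - 0.5 * d * M,
    )
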