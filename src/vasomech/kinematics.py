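"""Incompressible axisymmetric tube kinematics.

The reference configuration is the unloaded, traction-free tube (no residual
stress, no opening angle).  A deformed configuration is described by the
loaded inner radius ``a`` together with a fixed axial stretch ``lambda_z``;
incompressibility then determines the radial map completely.

All lengths are in millimetres, stretches are dimensionless.  Coordinates are
radii throughout; diameters only appear at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "VesselGeometry",
    "DeformationState",
    "deformed_outer_radius",
    "reference_radius",
    "inner_radius_from_outer",
    "stretches",
]


@dataclass(frozen=True)
class VesselGeometry:
    """Unloaded tube geometry.

    Parameters
    ----------
    A : float
        Unloaded inner radius (mm).
    B : float
        Unloaded outer radius (mm).
    """

    A: float
    B: float

    def __post_init__(self) -> None:
        if not (0.0 < self.A < self.B):
            raise ValueError(f"require 0 < A < B, got A={self.A}, B={self.B}")


@dataclass(frozen=True)
class DeformationState:
    """Loaded configuration at fixed axial stretch.

    Parameters
    ----------
    a : float
        Loaded inner radius (mm).
    lambda_z : float
        Axial stretch (held constant during pressurisation).
    """

    a: float
    lambda_z: float

    def __post_init__(self) -> None:
        if self.a <= 0.0:
            raise ValueError(f"loaded inner radius must be positive, got {self.a}")
        if self.lambda_z <= 0.0:
            raise ValueError(f"axial stretch must be positive, got {self.lambda_z}")


def deformed_outer_radius(geom: VesselGeometry, state: DeformationState) -> float:
    """Loaded outer radius ``b`` from volume conservation.

    ``b = sqrt((B^2 - A^2)/lambda_z + a^2)``.
    """
    return float(np.sqrt((geom.B**2 - geom.A**2) / state.lambda_z + state.a**2))


def inner_radius_from_outer(geom: VesselGeometry, b: float, lambda_z: float) -> float:
    """Invert :func:`deformed_outer_radius`: loaded inner radius from ``b``.

    Raises
    ------
    ValueError
        If ``b`` is too small to accommodate the wall volume at ``lambda_z``.
    """
    a_sq = b**2 - (geom.B**2 - geom.A**2) / lambda_z
    if a_sq <= 0.0:
        raise ValueError(
            f"outer radius b={b} incompatible with wall volume at lambda_z={lambda_z}"
        )
    return float(np.sqrt(a_sq))


def reference_radius(r, geom: VesselGeometry, state: DeformationState):
    """Reference radial coordinate ``R`` of the material point now at ``r``.

    ``R = sqrt((r^2 - a^2) * lambda_z + A^2)``.  Accepts scalars or arrays;
    every ``r`` must lie in the loaded wall ``[a, b]``.
    """
    r = np.asarray(r, dtype=float)
    b = deformed_outer_radius(geom, state)
    tol = 1e-12 * max(b, 1.0)
    if np.any(r < state.a - tol) or np.any(r > b + tol):
        raise ValueError(f"radial coordinate outside loaded wall [{state.a}, {b}]")
    R = np.sqrt((r**2 - state.a**2) * state.lambda_z + geom.A**2)
    return R if R.ndim else float(R)


def stretches(r, R, lambda_z):
    """Principal stretches ``(lambda_r, lambda_theta, lambda_z)``.

    ``lambda_theta = r/R`` and ``lambda_r = R/(r lambda_z)`` so the product is
    exactly one (incompressibility).
    """
    r = np.asarray(r, dtype=float)
    R = np.asarray(R, dtype=float)
    lam_t = r / R
    lam_r = R / (r * lambda_z)
    lam_z = np.broadcast_to(np.asarray(lambda_z, dtype=float), lam_t.shape)
    if lam_t.ndim:
        return lam_r, lam_t, np.array(lam_z)
    return float(lam_r), float(lam_t), float(lam_z)
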