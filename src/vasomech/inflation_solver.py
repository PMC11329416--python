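"""Pressure-radius relation of the inflated tube and its instabilities.

The transmural pressure at fixed axial stretch is the sum of the passive and
active load-bearing terms, ``P(a) = Gamma_pas(a) + Gamma_act(a)``.  This
module generates pressure-diameter curves, scans dP/da for limit-point
(fold) instabilities, and inverts P(a) = P_target for all equilibrium radii.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from scipy.optimize import brentq

from .active_models import (
    ActiveModel,
    NoClosedFormError,
    active_pressure_closed_form,
    active_pressure_derivative,
    active_pressure_quadrature,
)
from .kinematics import DeformationState, VesselGeometry, deformed_outer_radius
from .passive_wall import PassiveParams, passive_pressure, passive_pressure_derivative

__all__ = [
    "PressureDiameterCurve",
    "StabilityReport",
    "total_pressure",
    "total_pressure_derivative",
    "pressure_diameter_curve",
    "find_instability_regions",
    "solve_radius",
    "default_a_range",
    "NoRootError",
]

DEFAULT_SCAN_POINTS = 400
BISECTION_TOL_MM = 1e-6


class NoRootError(RuntimeError):
    """P_target is not attained anywhere in the scanned radius range."""


@dataclass
class PressureDiameterCurve:
    """Paired pressure / loaded outer-diameter samples at fixed axial stretch."""

    pressures: np.ndarray
    outer_diameters: np.ndarray  # 2b, mm
    lambda_z: float
    unit: str = "kPa"  # unit of `pressures`
    label: str = "relaxed"  # relaxed | contracted
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pressures = np.asarray(self.pressures, dtype=float)
        self.outer_diameters = np.asarray(self.outer_diameters, dtype=float)
        if self.pressures.shape != self.outer_diameters.shape:
            raise ValueError("pressures and outer_diameters must have equal length")
        if not np.all(np.isfinite(self.pressures)):
            raise ValueError("pressures must be finite")
        if np.any(self.outer_diameters <= 0.0):
            raise ValueError("diameters must be positive")

    @property
    def normalised_diameters(self) -> np.ndarray:
        """Diameters divided by the diameter at zero pressure (interpolated)."""
        order = np.argsort(self.pressures)
        d0 = float(
            np.interp(0.0, self.pressures[order], self.outer_diameters[order])
        )
        return self.outer_diameters / d0


@dataclass
class StabilityReport:
    """Result of scanning dP/da for fold instabilities."""

    unstable_intervals: List[Tuple[float, float]]
    a_grid: np.ndarray
    dP_da: np.ndarray
    monotone: bool


def total_pressure(
    geom: VesselGeometry,
    state: DeformationState,
    passive_params: PassiveParams,
    active_model: Optional[ActiveModel],
) -> float:
    """P = Gamma_pas + Gamma_act (kPa); closed form used where applicable."""
    P = passive_pressure(geom, state, passive_params)
    if active_model is not None:
        try:
            P += active_pressure_closed_form(active_model, geom, state)
        except NoClosedFormError:
            P += active_pressure_quadrature(active_model, geom, state)
    return P


def total_pressure_derivative(
    geom: VesselGeometry,
    state: DeformationState,
    passive_params: PassiveParams,
    active_model: Optional[ActiveModel],
) -> float:
    """dP/da (kPa/mm)."""
    d = passive_pressure_derivative(geom, state, passive_params)
    if active_model is not None:
        d += active_pressure_derivative(active_model, geom, state)
    return d


def default_a_range(geom: VesselGeometry) -> Tuple[float, float]:
    """Inner-radius range mapping the inner-wall stretch to [0.5, 2.2]."""
    return (0.5 * geom.A, 2.2 * geom.A)


def pressure_diameter_curve(
    geom: VesselGeometry,
    lambda_z: float,
    passive_params: PassiveParams,
    active_model: Optional[ActiveModel],
    a_grid,
    label: str = "relaxed",
) -> PressureDiameterCurve:
    """Evaluate P on an increasing grid of inner radii."""
    a_grid = np.asarray(a_grid, dtype=float)
    if np.any(np.diff(a_grid) <= 0.0):
        raise ValueError("a_grid must be strictly increasing")
    P = np.empty_like(a_grid)
    d = np.empty_like(a_grid)
    for j, a in enumerate(a_grid):
        st = DeformationState(a, lambda_z)
        P[j] = total_pressure(geom, st, passive_params, active_model)
        d[j] = 2.0 * deformed_outer_radius(geom, st)
    prov = {"A_mm": geom.A, "B_mm": geom.B}
    if active_model is not None:
        from .active_models import model_to_dict

        prov["active_model"] = model_to_dict(active_model)
    return PressureDiameterCurve(
        pressures=P,
        outer_diameters=d,
        lambda_z=lambda_z,
        unit="kPa",
        label=label,
        provenance=prov,
    )


def find_instability_regions(
    geom: VesselGeometry,
    lambda_z: float,
    passive_params: PassiveParams,
    active_model: Optional[ActiveModel],
    a_range: Optional[Tuple[float, float]] = None,
    n_scan: int = DEFAULT_SCAN_POINTS,
) -> StabilityReport:
    """Scan dP/da on a dense grid; bracket its sign changes by bisection.

    Returns the (disjoint, sorted) intervals of inner radius on which
    dP/da < 0, i.e. the descending limbs of a folded P(a) curve.
    """
    if a_range is None:
        a_range = default_a_range(geom)
    a_lo, a_hi = a_range
    grid = np.linspace(a_lo, a_hi, n_scan)

    def dPda(a):
        return total_pressure_derivative(
            geom, DeformationState(a, lambda_z), passive_params, active_model
        )

    vals = np.array([dPda(a) for a in grid])
    signs = np.sign(vals)

    crossings = []
    for j in range(len(grid) - 1):
        if signs[j] == 0.0:
            crossings.append(grid[j])
        elif signs[j] * signs[j + 1] < 0.0:
            crossings.append(
                brentq(dPda, grid[j], grid[j + 1], xtol=BISECTION_TOL_MM)
            )
    # assemble intervals where dP/da < 0
    edges = [a_lo] + crossings + [a_hi]
    intervals = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        if hi - lo < BISECTION_TOL_MM:
            continue
        mid = 0.5 * (lo + hi)
        if dPda(mid) < 0.0:
            intervals.append((lo, hi))
    # merge touching intervals
    merged: List[Tuple[float, float]] = []
    for lo, hi in intervals:
        if merged and lo - merged[-1][1] < BISECTION_TOL_MM:
            merged[-1] = (merged[-1][0], hi)
        else:
            merged.append((lo, hi))
    return StabilityReport(
        unstable_intervals=merged,
        a_grid=grid,
        dP_da=vals,
        monotone=not merged,
    )


def solve_radius(
    P_target: float,
    geom: VesselGeometry,
    lambda_z: float,
    passive_params: PassiveParams,
    active_model: Optional[ActiveModel],
    a_range: Optional[Tuple[float, float]] = None,
    n_scan: int = DEFAULT_SCAN_POINTS,
) -> List[float]:
    """All inner radii with P(a) = P_target in ``a_range``, sorted ascending.

    Roots are bracketed on the scan grid and polished by Brent's method to a
    residual below 1e-8 kPa.  Raises :class:`NoRootError` when the target
    pressure is not attained in range.
    """
    if a_range is None:
        a_range = default_a_range(geom)
    a_lo, a_hi = a_range
    grid = np.linspace(a_lo, a_hi, n_scan)

    def f(a):
        return (
            total_pressure(geom, DeformationState(a, lambda_z), passive_params, active_model)
            - P_target
        )

    vals = np.array([f(a) for a in grid])
    roots: List[float] = []
    for j in range(len(grid) - 1):
        if vals[j] == 0.0:
            roots.append(grid[j])
        elif vals[j] * vals[j + 1] < 0.0:
            roots.append(brentq(f, grid[j], grid[j + 1], xtol=1e-12, rtol=8.9e-16))
    if vals[-1] == 0.0:
        roots.append(grid[-1])
    if not roots:
        raise NoRootError(
            f"pressure {P_target} kPa not attained for a in [{a_lo}, {a_hi}] "
            f"(P range [{vals.min() + P_target:.6g}, {vals.max() + P_target:.6g}] kPa)"
        )
    return sorted(roots)
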