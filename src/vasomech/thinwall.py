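"""Thin-walled (membrane) approximation of the active pressure.

For a vessel characterised only by its radius-to-wall-thickness ratio
``b0/h0`` at zero pressure, the modelled active pressure is

    Gamma_act = t_act(lam_t) * (h0/b0) / (lam_t^2 * lam_z),

with the mean wall stretch ``lam_t`` approximated by the normalised outer
diameter ``b/b0``.  The experimental counterpart is the pointwise pressure
difference between a maximally contracted and a fully relaxed
pressure-diameter curve resampled at common normalised diameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import PchipInterpolator, interp1d

from .active_models import ActiveModel
from .inflation_solver import PressureDiameterCurve
from .units import to_kpa

__all__ = [
    "ThinWallVessel",
    "ActivePressureSamples",
    "thinwall_active_pressure",
    "experimental_active_pressure",
]


@dataclass(frozen=True)
class ThinWallVessel:
    """Membrane vessel: radius-to-thickness ratio at zero pressure."""

    radius_to_thickness: float  # b0/h0
    lambda_z: float = 1.0

    def __post_init__(self) -> None:
        if self.radius_to_thickness <= 1.0:
            raise ValueError("b0/h0 must exceed 1")
        if self.lambda_z <= 0.0:
            raise ValueError("lambda_z must be positive")


@dataclass
class ActivePressureSamples:
    """Experimental active pressure vs normalised diameter."""

    normalised_diameters: np.ndarray  # b/b0
    gamma_act: np.ndarray  # kPa
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.normalised_diameters = np.asarray(self.normalised_diameters, dtype=float)
        self.gamma_act = np.asarray(self.gamma_act, dtype=float)
        if self.normalised_diameters.shape != self.gamma_act.shape:
            raise ValueError("samples must have equal length")
        if np.any(self.normalised_diameters <= 0.0):
            raise ValueError("normalised diameters must be positive")


def thinwall_active_pressure(model: ActiveModel, vessel: ThinWallVessel, lam_t):
    """Modelled membrane active pressure (kPa) at wall stretch ``lam_t``."""
    lam_t = np.asarray(lam_t, dtype=float)
    t_act = model.cauchy_stress(lam_t)
    out = t_act / (vessel.radius_to_thickness * lam_t**2 * vessel.lambda_z)
    return out if out.ndim else float(out)


def _curve_pd(curve: PressureDiameterCurve, normalised: bool):
    """(pressure kPa, normalised diameter) arrays in pressure order."""
    P = to_kpa(curve.pressures, curve.unit)
    d = curve.outer_diameters if normalised else curve.normalised_diameters
    order = np.argsort(P)
    return P[order], d[order]


def experimental_active_pressure(
    relaxed: PressureDiameterCurve,
    contracted: PressureDiameterCurve,
    n_samples: int = 13,
    method: str = "pchip",
    normalised_input: bool = False,
) -> ActivePressureSamples:
    """Active pressure from paired relaxed/contracted curves.

    Both P(b/b0) relations are interpolated onto ``n_samples`` uniformly
    spaced normalised diameters spanning the diameter overlap; the sampled
    active pressure is the pointwise pressure difference (contracted minus
    relaxed, kPa).

    ``method`` is 'pchip' (monotone cubic, default) or 'linear'.  With
    ``normalised_input`` the curves' ``outer_diameters`` are taken as
    already normalised (b/b0).

    Raises
    ------
    ValueError
        On an empty diameter overlap or a non-monotone input curve.
    """
    out = []
    for curve, name in ((relaxed, "relaxed"), (contracted, "contracted")):
        P, d = _curve_pd(curve, normalised=normalised_input)
        if np.any(np.diff(d) <= 0.0):
            raise ValueError(f"{name} curve is not strictly monotone in diameter")
        out.append((P, d))
    (P_rel, d_rel), (P_con, d_con) = out

    lo = max(d_rel.min(), d_con.min())
    hi = min(d_rel.max(), d_con.max())
    if hi <= lo:
        raise ValueError("relaxed and contracted curves have no diameter overlap")

    d_common = np.linspace(lo, hi, n_samples)
    if method == "pchip":
        f_rel = PchipInterpolator(d_rel, P_rel)
        f_con = PchipInterpolator(d_con, P_con)
    elif method == "linear":
        f_rel = interp1d(d_rel, P_rel)
        f_con = interp1d(d_con, P_con)
    else:
        raise ValueError(f"unknown interpolation method {method!r}")

    gamma = f_con(d_common) - f_rel(d_common)
    return ActivePressureSamples(
        normalised_diameters=d_common,
        gamma_act=np.asarray(gamma, dtype=float),
        provenance={
            "method": method,
            "n_samples": n_samples,
            "overlap": (float(lo), float(hi)),
        },
    )
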