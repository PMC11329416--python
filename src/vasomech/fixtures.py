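"""Deterministic synthetic stand-ins for the experimental inputs.

Two scenarios are provided:

* ``mouse_like`` — a thick-walled vessel with a four-fibre passive law whose
  inflation response at axial stretch 1.60 has the physiological shape of a
  murine descending thoracic aorta (compliant below ~60 mmHg, stiffening
  above ~120 mmHg).  The numbers are frozen fixture constants chosen once to
  satisfy documented sanity windows; they are NOT the published
  supplementary parameters of any particular animal.

* ``cox_like`` — a thin-walled vessel producing paired relaxed/contracted
  pressure-normalised-diameter curves sampled every 20 mmHg over 0-240 mmHg
  (13 points), with the contracted curve built by adding a known active
  model's membrane pressure to the relaxed one.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy.optimize import brentq

from .active_models import ActiveModel
from .estimation import ContractionDatum
from .inflation_solver import PressureDiameterCurve, default_a_range, solve_radius
from .kinematics import DeformationState, VesselGeometry, deformed_outer_radius
from .passive_wall import FibreFamily, PassiveParams, passive_extra_stress
from .thinwall import ThinWallVessel, thinwall_active_pressure
from .units import to_kpa

__all__ = [
    "FixtureSpec",
    "MOUSE_LIKE_LAMBDA_Z",
    "make_mouse_like_vessel",
    "make_cox_like_passive",
    "generate_contraction_datum",
    "generate_cox_like_curves",
    "thinwall_passive_pressure",
]

#: in vivo axial stretch of the mouse-like scenario
MOUSE_LIKE_LAMBDA_Z = 1.60

# Frozen mouse-like fixture constants (see module docstring).
_MOUSE_GEOM = dict(A=0.390, B=0.490)  # unloaded radii, mm
_MOUSE_PASSIVE = dict(
    mu=20.0,  # kPa
    families=(
        FibreFamily(k1=18.0, k2=0.20, alpha_deg=0.0),  # axial
        FibreFamily(k1=12.0, k2=0.45, alpha_deg=90.0),  # circumferential
        FibreFamily(k1=7.0, k2=0.80, alpha_deg=40.0),  # diagonal
        FibreFamily(k1=7.0, k2=0.80, alpha_deg=-40.0),  # diagonal
    ),
)

# Frozen cox-like (dog, thin-wall) fixture constants.
_COX_PASSIVE = dict(
    mu=30.0,
    families=(
        FibreFamily(k1=20.0, k2=0.8, alpha_deg=0.0),
        FibreFamily(k1=25.0, k2=1.2, alpha_deg=90.0),
        FibreFamily(k1=12.0, k2=1.5, alpha_deg=45.0),
        FibreFamily(k1=12.0, k2=1.5, alpha_deg=-45.0),
    ),
)
_COX_PRESSURES_MMHG = np.arange(0.0, 241.0, 20.0)  # 13 samples


@dataclass(frozen=True)
class FixtureSpec:
    """Declarative description of a synthetic scenario (CLI plumbing)."""

    scenario: str  # mouse_like | cox_like
    seed: int = 0
    noise_sd: float = 0.0  # mmHg, added to pressures
    pressure_grid_mmHg: Tuple[float, ...] = tuple(_COX_PRESSURES_MMHG)

    def __post_init__(self) -> None:
        if self.scenario not in ("mouse_like", "cox_like"):
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.noise_sd < 0.0:
            raise ValueError("noise_sd must be non-negative")


def make_mouse_like_vessel() -> Tuple[VesselGeometry, PassiveParams, float]:
    """Thick-walled mouse-like vessel: geometry, passive law, axial stretch."""
    geom = VesselGeometry(**_MOUSE_GEOM)
    passive = PassiveParams(mu=_MOUSE_PASSIVE["mu"], families=_MOUSE_PASSIVE["families"])
    return geom, passive, MOUSE_LIKE_LAMBDA_Z


def make_cox_like_passive() -> PassiveParams:
    """Passive law of the thin-walled cox-like scenario (lambda_z = 1)."""
    return PassiveParams(mu=_COX_PASSIVE["mu"], families=_COX_PASSIVE["families"])


def thinwall_passive_pressure(
    lam_t, passive: PassiveParams, vessel: ThinWallVessel
):
    """Membrane passive pressure (kPa) at mean wall stretch ``lam_t``.

    Same membrane relation as the active counterpart:
    ``P = (ttt* - trr*) / ((b0/h0) lam_t^2 lam_z)`` with
    ``lam_r = 1/(lam_t lam_z)``.
    """
    lam_t = np.asarray(lam_t, dtype=float)
    lam_z = vessel.lambda_z
    lam_r = 1.0 / (lam_t * lam_z)
    trr, ttt, _ = passive_extra_stress(lam_r, lam_t, lam_z, passive)
    out = (ttt - trr) / (vessel.radius_to_thickness * lam_t**2 * lam_z)
    return out if out.ndim else float(out)


def generate_contraction_datum(
    geom: VesselGeometry,
    passive: PassiveParams,
    lambda_z: float,
    true_model: ActiveModel,
    P_hold_mmHg: float = 90.0,
    allow_unstable: bool = False,
) -> ContractionDatum:
    """Forward-simulate the contracted diameter at a held pressure.

    Returns the exact (noise-free) fractional outer-diameter reduction, for
    parameter-recovery round trips.  Raises if the contracted state is
    non-unique, unless ``allow_unstable`` (then the largest-radius root, the
    branch reached quasi-statically from the relaxed state, is used).
    """
    P = to_kpa(P_hold_mmHg, "mmHg")
    a_range = default_a_range(geom)
    a_rel = solve_radius(P, geom, lambda_z, passive, None, a_range)[-1]
    roots = solve_radius(P, geom, lambda_z, passive, true_model, a_range)
    if len(roots) > 1 and not allow_unstable:
        raise RuntimeError(
            f"contracted state at {P_hold_mmHg} mmHg is non-unique "
            f"({len(roots)} equilibria); pass allow_unstable=True to proceed"
        )
    a_con = roots[-1]
    b_rel = deformed_outer_radius(geom, DeformationState(a_rel, lambda_z))
    b_con = deformed_outer_radius(geom, DeformationState(a_con, lambda_z))
    return ContractionDatum(
        pressure_mmHg=P_hold_mmHg,
        lambda_z=lambda_z,
        diameter_reduction=1.0 - b_con / b_rel,
    )


def _solve_lam(P_target: float, pressure_fn, lam_range=(0.25, 4.0), n=800) -> float:
    """Largest root of pressure_fn(lam) = P_target on lam_range."""
    lam = np.linspace(lam_range[0], lam_range[1], n)
    v = pressure_fn(lam) - P_target
    for j in range(len(lam) - 2, -1, -1):
        if v[j] == 0.0:
            return float(lam[j])
        if v[j] * v[j + 1] < 0.0:
            return float(brentq(lambda x: pressure_fn(x) - P_target, lam[j], lam[j + 1], xtol=1e-13))
    raise RuntimeError(f"membrane pressure {P_target} kPa not attained on {lam_range}")


def generate_cox_like_curves(
    vessel: ThinWallVessel,
    true_model: Optional[ActiveModel],
    noise_sd: float = 0.0,
    seed: int = 0,
    passive: Optional[PassiveParams] = None,
) -> Tuple[PressureDiameterCurve, PressureDiameterCurve]:
    """Paired relaxed/contracted membrane curves on the 0-240 mmHg grid.

    Diameters are normalised (b/b0 with b0 at zero pressure, so the relaxed
    curve passes through (0 mmHg, 1)).  Gaussian noise with standard
    deviation ``noise_sd`` (mmHg) is added to the recorded pressures when
    positive; the seed makes the pair reproducible.
    """
    passive = passive if passive is not None else make_cox_like_passive()
    grid_kpa = to_kpa(_COX_PRESSURES_MMHG, "mmHg")

    def p_rel(lam):
        return thinwall_passive_pressure(lam, passive, vessel)

    def p_con(lam):
        out = thinwall_passive_pressure(lam, passive, vessel)
        if true_model is not None:
            out = out + thinwall_active_pressure(true_model, vessel, lam)
        return out

    d_rel = np.array([_solve_lam(P, p_rel) for P in grid_kpa])
    d_con = np.array([_solve_lam(P, p_con) for P in grid_kpa])

    p_rel_mmHg = _COX_PRESSURES_MMHG.copy()
    p_con_mmHg = _COX_PRESSURES_MMHG.copy()
    if noise_sd > 0.0:
        rng = np.random.default_rng(seed)
        p_rel_mmHg = p_rel_mmHg + rng.normal(0.0, noise_sd, size=p_rel_mmHg.shape)
        p_con_mmHg = p_con_mmHg + rng.normal(0.0, noise_sd, size=p_con_mmHg.shape)

    prov = {"scenario": "cox_like", "seed": seed, "noise_sd_mmHg": noise_sd}
    relaxed = PressureDiameterCurve(
        pressures=p_rel_mmHg,
        outer_diameters=d_rel,
        lambda_z=vessel.lambda_z,
        unit="mmHg",
        label="relaxed",
        provenance=dict(prov),
    )
    contracted = PressureDiameterCurve(
        pressures=p_con_mmHg,
        outer_diameters=d_con,
        lambda_z=vessel.lambda_z,
        unit="mmHg",
        label="contracted",
        provenance=dict(prov),
    )
    return relaxed, contracted
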