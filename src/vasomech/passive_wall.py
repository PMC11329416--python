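"""Four-fibre-family passive hyperelasticity of the arterial wall.

Strain energy per unit reference volume (kPa):

    Psi = mu/2 (I1 - 3) + sum_i k1_i/(4 k2_i) [exp(k2_i (I4_i - 1)^2) - 1]

with ``I1 = lr^2 + lt^2 + lz^2`` and ``I4_i = lt^2 sin^2(alpha_i)
+ lz^2 cos^2(alpha_i)`` for a fibre family at angle ``alpha_i`` from the
axial direction.  Fibre terms are evaluated literally (no tension-only
switch) unless ``tension_only`` is set, in which case a family contributes
nothing while ``I4 < 1``.

The passive load-bearing term is

    Gamma_pas = int_a^b (t_theta^pas* - t_r^pas*) / r dr

evaluated by adaptive quadrature with the integrand expressed through the
deformed radial coordinate only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import quad

from .kinematics import (
    DeformationState,
    VesselGeometry,
    deformed_outer_radius,
    reference_radius,
    stretches,
)

__all__ = [
    "FibreFamily",
    "PassiveParams",
    "WallStressField",
    "passive_energy",
    "passive_extra_stress",
    "passive_pressure",
    "passive_pressure_derivative",
    "transmural_stress_field",
]

_QUAD_KW = dict(epsabs=1e-12, epsrel=1e-10, limit=200)


@dataclass(frozen=True)
class FibreFamily:
    """One exponential collagen fibre family.

    ``alpha_deg`` is the angle from the axial direction: 0 is axial,
    90 is circumferential.
    """

    k1: float  # kPa
    k2: float  # dimensionless, > 0
    alpha_deg: float

    def __post_init__(self) -> None:
        if self.k1 < 0.0:
            raise ValueError("k1 must be non-negative")
        if self.k2 <= 0.0:
            raise ValueError("k2 must be positive")


@dataclass(frozen=True)
class PassiveParams:
    """Isotropic matrix stiffness plus a list of fibre families."""

    mu: float  # kPa
    families: tuple = field(default_factory=tuple)
    tension_only: bool = False

    def __post_init__(self) -> None:
        if self.mu < 0.0:
            raise ValueError("mu must be non-negative")
        object.__setattr__(self, "families", tuple(self.families))

    def to_dict(self) -> dict:
        return {
            "mu_kPa": self.mu,
            "families": [
                {"k1_kPa": f.k1, "k2": f.k2, "alpha_deg": f.alpha_deg}
                for f in self.families
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PassiveParams":
        fams = tuple(
            FibreFamily(f["k1_kPa"], f["k2"], f["alpha_deg"])
            for f in d.get("families", [])
        )
        return cls(mu=d["mu_kPa"], families=fams, tension_only=d.get("tension_only", False))


@dataclass
class WallStressField:
    """Total Cauchy stress components across the wall on a radial grid."""

    r: np.ndarray  # mm
    trr: np.ndarray  # kPa
    ttt: np.ndarray  # kPa (circumferential)
    tzz: np.ndarray  # kPa
    p: np.ndarray  # Lagrange multiplier, kPa


def _fibre_terms(lam_t, lam_z, params: PassiveParams):
    """Yield (stress factor k1 (I4-1) exp(k2 (I4-1)^2), sin^2, cos^2) per family.

    The factor is 2 dPsi/dI4 for the k1/(4 k2) energy normalisation, so the
    extra stress stays the exact push-forward of the stored energy.
    """
    for fam in params.families:
        al = math.radians(fam.alpha_deg)
        s2, c2 = math.sin(al) ** 2, math.cos(al) ** 2
        I4 = lam_t**2 * s2 + lam_z**2 * c2
        e = I4 - 1.0
        if params.tension_only:
            e = np.where(np.asarray(e) < 0.0, 0.0, e)
        factor = fam.k1 * e * np.exp(fam.k2 * e**2)
        yield factor, s2, c2


def passive_energy(lam_r, lam_t, lam_z, params: PassiveParams):
    """Strain energy density (kPa) at the given principal stretches."""
    lam_r, lam_t, lam_z = (np.asarray(x, dtype=float) for x in (lam_r, lam_t, lam_z))
    I1 = lam_r**2 + lam_t**2 + lam_z**2
    psi = 0.5 * params.mu * (I1 - 3.0)
    for fam in params.families:
        al = math.radians(fam.alpha_deg)
        I4 = lam_t**2 * math.sin(al) ** 2 + lam_z**2 * math.cos(al) ** 2
        e = I4 - 1.0
        if params.tension_only:
            e = np.where(np.asarray(e) < 0.0, 0.0, e)
        psi = psi + fam.k1 / (4.0 * fam.k2) * (np.exp(fam.k2 * e**2) - 1.0)
    return psi if np.ndim(psi) else float(psi)


def passive_extra_stress(lam_r, lam_t, lam_z, params: PassiveParams):
    """Passive Cauchy extra stress ``(trr*, ttt*, tzz*)`` in kPa.

    Push-forward ``2 F dPsi/dC F^T`` for diagonal ``F``; the isotropic term
    gives ``mu lam^2`` on each axis, each fibre family adds
    ``k1 (I4-1) exp(k2 (I4-1)^2)`` weighted by ``lam_t^2 sin^2`` /
    ``lam_z^2 cos^2`` on the circumferential / axial axes.
    """
    lam_r, lam_t, lam_z = (np.asarray(x, dtype=float) for x in (lam_r, lam_t, lam_z))
    trr = params.mu * lam_r**2
    ttt = params.mu * lam_t**2
    tzz = params.mu * lam_z**2
    for factor, s2, c2 in _fibre_terms(lam_t, lam_z, params):
        ttt = ttt + factor * lam_t**2 * s2
        tzz = tzz + factor * lam_z**2 * c2
    if np.ndim(ttt):
        trr = np.broadcast_to(trr, ttt.shape).copy()
        return trr, ttt, tzz
    return float(trr), float(ttt), float(tzz)


def _gamma_integrand(geom, state, params):
    def integrand(r):
        R = np.sqrt((r**2 - state.a**2) * state.lambda_z + geom.A**2)
        lam_r, lam_t, lam_z = stretches(r, R, state.lambda_z)
        trr, ttt, _ = passive_extra_stress(lam_r, lam_t, lam_z, params)
        return (ttt - trr) / r

    return integrand


def passive_pressure(geom: VesselGeometry, state: DeformationState, params: PassiveParams) -> float:
    """Passive contribution to transmural pressure, Gamma_pas (kPa)."""
    b = deformed_outer_radius(geom, state)
    val, err = quad(_gamma_integrand(geom, state, params), state.a, b, **_QUAD_KW)
    if not np.isfinite(val) or (abs(val) > 1e-10 and err > 1e-6 * abs(val)):
        raise RuntimeError(
            f"passive pressure quadrature did not converge: value={val}, abserr={err}"
        )
    return float(val)


def passive_pressure_derivative(
    geom: VesselGeometry, state: DeformationState, params: PassiveParams
) -> float:
    """d(Gamma_pas)/da (kPa/mm) by adaptive central differences.

    Step is halved once; the two estimates are combined by Richardson
    extrapolation (the halving also acts as a consistency check).
    """
    a = state.a
    h = 1e-4 * max(a, 1.0)

    def g(aa):
        return passive_pressure(geom, DeformationState(aa, state.lambda_z), params)

    d_h = (g(a + h) - g(a - h)) / (2.0 * h)
    d_h2 = (g(a + h / 2.0) - g(a - h / 2.0)) / h
    return float((4.0 * d_h2 - d_h) / 3.0)


def transmural_stress_field(
    geom: VesselGeometry,
    state: DeformationState,
    params: PassiveParams,
    active_model,
    P: float,
    n: int = 101,
) -> WallStressField:
    """Total stresses and Lagrange multiplier across the wall at pressure ``P``.

    ``P`` (kPa) must match the equilibrium pressure of the configuration; a
    mismatch beyond quadrature tolerance raises ``ValueError``.  The active
    model (may be ``None``) contributes circumferential stress only.
    """
    from .active_models import active_pressure_quadrature  # local import: avoid cycle

    b = deformed_outer_radius(geom, state)
    P_eq = passive_pressure(geom, state, params)
    if active_model is not None:
        P_eq += active_pressure_quadrature(active_model, geom, state)
    if abs(P - P_eq) > 1e-6 * max(1.0, abs(P_eq)):
        raise ValueError(
            f"prescribed pressure {P} kPa inconsistent with equilibrium {P_eq} kPa"
        )

    r = np.linspace(state.a, b, n)
    R = reference_radius(r, geom, state)
    lam_r, lam_t, lam_z = stretches(r, R, state.lambda_z)
    trr_s, ttt_s, tzz_s = passive_extra_stress(lam_r, lam_t, lam_z, params)
    ttt_act = np.zeros_like(r)
    if active_model is not None:
        from .active_models import active_cauchy_stress

        ttt_act = np.asarray(active_cauchy_stress(active_model, lam_t), dtype=float)
        ttt_act = np.broadcast_to(ttt_act, r.shape).copy()

    integrand = _gamma_integrand(geom, state, params)

    def full_integrand(rr):
        RR = np.sqrt((rr**2 - state.a**2) * state.lambda_z + geom.A**2)
        lt = rr / RR
        act = 0.0
        if active_model is not None:
            from .active_models import active_cauchy_stress

            act = active_cauchy_stress(active_model, lt)
        return integrand(rr) + act / rr

    part = np.empty_like(r)
    part[0] = 0.0
    for j in range(1, n):
        part[j] = part[j - 1] + quad(full_integrand, r[j - 1], r[j], **_QUAD_KW)[0]

    # p(r) = trr_pas*(r) + trr_act*(r) + P - int_a^r (ttt - trr)/r dr
    p = trr_s + P - part
    trr = -p + trr_s
    ttt = -p + ttt_s + ttt_act
    tzz = -p + tzz_s
    return WallStressField(r=r, trr=trr, ttt=ttt, tzz=tzz, p=p)
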