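"""Active (smooth-muscle) stress models for the arterial wall.

Six constitutive families share one contract: a circumferential active
Cauchy stress ``t_act(lam_t)``, an active energy ``Psi_act(lam_t)``, the
active load-bearing term

    Gamma_act = int_a^b t_act(lam_theta(r)) / r dr,

its derivative with respect to the loaded inner radius ``a``, and — where
one exists — an analytic stabilisation condition for the sign of that
derivative.

Families
--------
ConstantCauchyModel    t = Tc                (constant in the current config)
ConstantFirstPKModel   t = Ti lam_t          (constant 1st Piola-Kirchhoff)
ConstantSecondPKModel  t = Tr lam_t^2        (constant 2nd Piola-Kirchhoff)
RachevModel            t = TRv lam_t f(lam_t), bell-shaped force-length f
ZulligerModel          t = S1 S2 TZr (lam_t lam_pre - 1), gated ascending limb
FranchiniModel         t = S1 2 TFr1 lam_t^2 [1 + a1 e - b1 e^m1], e = lam_t^2 - 1

Closed forms exist for all constant-stress models, for Rachev and Zulliger
whenever the whole wall deforms inside the force-length support / gating
window, and for Franchini when m1 = 2.  ``active_pressure_quadrature`` is
the general fallback and splits the integral at support boundaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.integrate import quad

from .kinematics import DeformationState, VesselGeometry, deformed_outer_radius

__all__ = [
    "ActiveModel",
    "ConstantCauchyModel",
    "ConstantFirstPKModel",
    "ConstantSecondPKModel",
    "RachevModel",
    "ZulligerModel",
    "FranchiniModel",
    "StabilityCondition",
    "NoClosedFormError",
    "active_cauchy_stress",
    "active_energy",
    "active_pressure_closed_form",
    "active_pressure_quadrature",
    "active_pressure_derivative",
    "stability_condition",
    "model_from_dict",
    "model_to_dict",
    "FAMILY_NAMES",
]

_QUAD_KW = dict(epsabs=1e-13, epsrel=1e-11, limit=300)


class NoClosedFormError(ValueError):
    """A closed-form expression is not applicable for this model/state.

    Callers should fall back to :func:`active_pressure_quadrature`.
    """


@dataclass(frozen=True)
class StabilityCondition:
    """Result of evaluating an analytic stabilisation inequality.

    ``is_stabilising`` is True iff d(Gamma_act)/da > 0 at the given state.
    ``lhs``/``rhs`` are the two sides of the printed inequality (None when
    the model has a fixed-sign derivative and no inequality to evaluate).
    ``analytic`` is False when the result comes from the numerical
    derivative fallback rather than a printed condition.
    """

    is_stabilising: bool
    lhs: Optional[float]
    rhs: Optional[float]
    analytic: bool = True


def _geom_terms(geom: VesselGeometry, state: DeformationState):
    A, B = geom.A, geom.B
    a = state.a
    lz = state.lambda_z
    b = deformed_outer_radius(geom, state)
    return A, B, a, b, lz, math.sqrt(lz)


def _ln1(A, B, a, b, sl):
    """log((B + sqrt(lz) b) / (A + sqrt(lz) a)) — recurring 1st-PK integral."""
    return math.log((B + sl * b) / (A + sl * a))


class ActiveModel:
    """Common interface; concrete families override the hooks below."""

    family: str = ""

    # -- constitutive surface -------------------------------------------------
    def cauchy_stress(self, lam_t):
        raise NotImplementedError

    def energy(self, lam_t):
        raise NotImplementedError

    # -- wall integrals -------------------------------------------------------
    def _support_breakpoints(self, geom, state):
        """Radii in (a, b) where the stress switches on/off (default: none)."""
        return []

    def gamma_closed_form(self, geom, state) -> float:
        raise NoClosedFormError(
            f"{self.family}: no closed-form Gamma_act; use active_pressure_quadrature"
        )

    def dgamma_da_closed_form(self, geom, state) -> float:
        raise NoClosedFormError(
            f"{self.family}: no closed-form derivative; use finite differences"
        )

    def stability(self, geom, state) -> StabilityCondition:
        d = active_pressure_derivative(self, geom, state)
        return StabilityCondition(is_stabilising=d > 0.0, lhs=None, rhs=None, analytic=False)

    # -- serialisation --------------------------------------------------------
    def params_dict(self) -> dict:
        raise NotImplementedError


@dataclass(frozen=True)
class ConstantCauchyModel(ActiveModel):
    """Constant active Cauchy stress ``Tc`` (kPa)."""

    Tc: float
    family = "constant_cauchy"

    def __post_init__(self):
        if self.Tc < 0.0:
            raise ValueError("Tc must be non-negative")

    def cauchy_stress(self, lam_t):
        return self.Tc * np.ones_like(np.asarray(lam_t, dtype=float))

    def energy(self, lam_t):
        lam_t = np.asarray(lam_t, dtype=float)
        return 0.5 * self.Tc * np.log(lam_t**2)

    def gamma_closed_form(self, geom, state):
        _, _, a, b, _, _ = _geom_terms(geom, state)
        return self.Tc * math.log(b / a)

    def dgamma_da_closed_form(self, geom, state):
        _, _, a, b, _, _ = _geom_terms(geom, state)
        return self.Tc * (a**2 - b**2) / (a * b**2)

    def stability(self, geom, state):
        # derivative strictly negative for Tc > 0 (neutral at Tc = 0)
        return StabilityCondition(is_stabilising=False, lhs=None, rhs=None)

    def params_dict(self):
        return {"Tc_kPa": self.Tc}


@dataclass(frozen=True)
class ConstantFirstPKModel(ActiveModel):
    """Constant active 1st Piola-Kirchhoff stress ``Ti`` (kPa)."""

    Ti: float
    family = "constant_1pk"

    def __post_init__(self):
        if self.Ti < 0.0:
            raise ValueError("Ti must be non-negative")

    def cauchy_stress(self, lam_t):
        return self.Ti * np.asarray(lam_t, dtype=float)

    def energy(self, lam_t):
        return self.Ti * (np.asarray(lam_t, dtype=float) - 1.0)

    def gamma_closed_form(self, geom, state):
        A, B, a, b, _, sl = _geom_terms(geom, state)
        return self.Ti / sl * _ln1(A, B, a, b, sl)

    def dgamma_da_closed_form(self, geom, state):
        A, B, a, b, _, sl = _geom_terms(geom, state)
        num = a * (A + sl * a) - b * (B + sl * b)
        den = b * (A + sl * a) * (B + sl * b)
        return self.Ti * num / den

    def stability(self, geom, state):
        return StabilityCondition(is_stabilising=False, lhs=None, rhs=None)

    def params_dict(self):
        return {"Ti_kPa": self.Ti}


@dataclass(frozen=True)
class ConstantSecondPKModel(ActiveModel):
    """Constant active 2nd Piola-Kirchhoff stress ``Tr`` (kPa).

    Gamma_act = Tr/(2 lz) ln(B^2/A^2) is independent of the deformed state,
    so the model can never destabilise the inflation response.
    """

    Tr: float
    family = "constant_2pk"

    def __post_init__(self):
        if self.Tr < 0.0:
            raise ValueError("Tr must be non-negative")

    def cauchy_stress(self, lam_t):
        return self.Tr * np.asarray(lam_t, dtype=float) ** 2

    def energy(self, lam_t):
        return 0.5 * self.Tr * (np.asarray(lam_t, dtype=float) ** 2 - 1.0)

    def gamma_closed_form(self, geom, state):
        A, B, _, _, lz, _ = _geom_terms(geom, state)
        return self.Tr / (2.0 * lz) * math.log(B**2 / A**2)

    def dgamma_da_closed_form(self, geom, state):
        return 0.0

    def stability(self, geom, state):
        return StabilityCondition(is_stabilising=False, lhs=None, rhs=None)

    def params_dict(self):
        return {"Tr_kPa": self.Tr}


@dataclass(frozen=True)
class RachevModel(ActiveModel):
    """Bell-shaped force-length model ``t = TRv lam_t f(lam_t)``.

    ``f(x) = 1 - ((lam_m - x)/(lam_m - lam_0))^2`` on
    ``[lam_0, 2 lam_m - lam_0]`` and zero outside; ``f(lam_m) = 1``.
    """

    TRv: float
    lambda_m: float
    lambda_0: float
    family = "rachev"

    def __post_init__(self):
        if self.TRv < 0.0:
            raise ValueError("TRv must be non-negative")
        if not self.lambda_0 < self.lambda_m:
            raise ValueError("require lambda_0 < lambda_m")

    @property
    def support(self):
        return (self.lambda_0, 2.0 * self.lambda_m - self.lambda_0)

    def force_length(self, lam_t):
        lam_t = np.asarray(lam_t, dtype=float)
        lo, hi = self.support
        f = 1.0 - ((self.lambda_m - lam_t) / (self.lambda_m - self.lambda_0)) ** 2
        return np.where((lam_t >= lo) & (lam_t <= hi), f, 0.0)

    def cauchy_stress(self, lam_t):
        lam_t = np.asarray(lam_t, dtype=float)
        return self.TRv * lam_t * self.force_length(lam_t)

    def energy(self, lam_t):
        # Psi = TRv * int_1^lam_t f(s) ds, with antiderivative
        # F(s) = s + (lam_m - s)^3 / (3 (lam_m - lam_0)^2) clamped to support.
        lm, l0 = self.lambda_m, self.lambda_0
        lo, hi = self.support

        def F(s):
            return s + (lm - s) ** 3 / (3.0 * (lm - l0) ** 2)

        def prim(s):
            s = np.clip(s, lo, hi)
            return F(s)

        lam_t = np.asarray(lam_t, dtype=float)
        val = self.TRv * (prim(lam_t) - prim(1.0))
        return val if val.ndim else float(val)

    def _wall_lam_range(self, geom, state):
        b = deformed_outer_radius(geom, state)
        lt_in = state.a / geom.A
        lt_out = b / geom.B
        return min(lt_in, lt_out), max(lt_in, lt_out)

    def _support_breakpoints(self, geom, state):
        return _lam_theta_breakpoints(geom, state, self.support)

    def gamma_closed_form(self, geom, state):
        lo, hi = self.support
        lt_min, lt_max = self._wall_lam_range(geom, state)
        if lt_min < lo - 1e-12 or lt_max > hi + 1e-12:
            raise NoClosedFormError(
                "rachev: wall stretch range outside force-length support; "
                "use active_pressure_quadrature"
            )
        A, B, a, b, lz, sl = _geom_terms(geom, state)
        lm, l0 = self.lambda_m, self.lambda_0
        w2 = (lm - l0) ** 2
        term1 = (
            self.TRv / (sl * w2) * (w2 - lm**2 - 1.0 / lz) * _ln1(A, B, a, b, sl)
        )
        term2 = self.TRv / (lz * w2) * (lm * math.log(B**2 / A**2) + b / B - a / A)
        return term1 + term2

    def dgamma_da_closed_form(self, geom, state):
        lo, hi = self.support
        lt_min, lt_max = self._wall_lam_range(geom, state)
        if lt_min < lo - 1e-12 or lt_max > hi + 1e-12:
            raise NoClosedFormError("rachev: wall stretch range outside support")
        A, B, a, b, lz, sl = _geom_terms(geom, state)
        lm, l0 = self.lambda_m, self.lambda_0
        w2 = (lm - l0) ** 2
        num = a * (A + sl * a) - b * (B + sl * b)
        den = b * (A + sl * a) * (B + sl * b)
        return self.TRv / w2 * (
            num / den * (w2 - lm**2 - 1.0 / lz) + (A * a - B * b) / (A * B * b * lz)
        )

    def stability(self, geom, state):
        A, B, a, b, lz, sl = _geom_terms(geom, state)
        lm, l0 = self.lambda_m, self.lambda_0
        lhs = lm**2 - (lm - l0) ** 2
        rhs = (
            a
            * b
            * (B * (B + sl * b) - A * (A + sl * a))
            / (sl * A * B * (b * (B + sl * b) - a * (A + sl * a)))
        )
        return StabilityCondition(is_stabilising=lhs > rhs, lhs=lhs, rhs=rhs)

    def params_dict(self):
        return {"TRv_kPa": self.TRv, "lambda_m": self.lambda_m, "lambda_0": self.lambda_0}


@dataclass(frozen=True)
class ZulligerModel(ActiveModel):
    """Gated ascending-limb model ``t = S1 S2 TZr (lam_t lam_pre - 1)``.

    ``S2`` is an indicator on the muscle-level stretch
    ``lam_hat = lam_t * lambda_pre`` being inside
    ``[lambda_hat_lb, lambda_hat_ub]`` (defaults: unbounded).  Within the
    gate the stress decomposes as a constant 1st-PK contribution with
    ``Ti = S1 TZr lambda_pre`` minus a constant Cauchy contribution with
    ``Tc = S1 TZr``.
    """

    TZr: float
    lambda_pre: float
    S1: float = 1.0
    lambda_hat_lb: float = -math.inf
    lambda_hat_ub: float = math.inf
    family = "zulliger"

    def __post_init__(self):
        if self.TZr < 0.0:
            raise ValueError("TZr must be non-negative")
        if self.lambda_pre <= 0.0:
            raise ValueError("lambda_pre must be positive")
        if not 0.0 <= self.S1 <= 1.0:
            raise ValueError("S1 must lie in [0, 1]")
        if self.lambda_hat_lb > self.lambda_hat_ub:
            raise ValueError("lambda_hat_lb must not exceed lambda_hat_ub")

    @property
    def gate(self):
        """Gating window expressed in tissue stretch lam_t."""
        return (self.lambda_hat_lb / self.lambda_pre, self.lambda_hat_ub / self.lambda_pre)

    def _s2(self, lam_t):
        lam_hat = np.asarray(lam_t, dtype=float) * self.lambda_pre
        return ((lam_hat >= self.lambda_hat_lb) & (lam_hat <= self.lambda_hat_ub)).astype(float)

    def cauchy_stress(self, lam_t):
        lam_t = np.asarray(lam_t, dtype=float)
        return self.S1 * self._s2(lam_t) * self.TZr * (lam_t * self.lambda_pre - 1.0)

    def energy(self, lam_t):
        lam_hat = np.asarray(lam_t, dtype=float) * self.lambda_pre
        return self.S1 * self._s2(lam_t) * self.TZr * (lam_hat - np.log(lam_hat) - 1.0)

    def _support_breakpoints(self, geom, state):
        return _lam_theta_breakpoints(geom, state, self.gate)

    def _gate_ok(self, geom, state):
        b = deformed_outer_radius(geom, state)
        lt = sorted((state.a / geom.A, b / geom.B))
        lo, hi = self.gate
        return lt[0] >= lo - 1e-12 and lt[1] <= hi + 1e-12

    def gamma_closed_form(self, geom, state):
        if not self._gate_ok(geom, state):
            raise NoClosedFormError(
                "zulliger: wall stretch range outside gating window; "
                "use active_pressure_quadrature"
            )
        g1 = ConstantFirstPKModel(1.0).gamma_closed_form(geom, state)
        gc = ConstantCauchyModel(1.0).gamma_closed_form(geom, state)
        return self.S1 * self.TZr * (self.lambda_pre * g1 - gc)

    def dgamma_da_closed_form(self, geom, state):
        if not self._gate_ok(geom, state):
            raise NoClosedFormError("zulliger: wall stretch range outside gating window")
        d1 = ConstantFirstPKModel(1.0).dgamma_da_closed_form(geom, state)
        dc = ConstantCauchyModel(1.0).dgamma_da_closed_form(geom, state)
        return self.S1 * self.TZr * (self.lambda_pre * d1 - dc)

    def stability(self, geom, state):
        A, B, a, b, lz, sl = _geom_terms(geom, state)
        lhs = self.lambda_pre
        rhs = (
            (b**2 - a**2)
            * (A + sl * a)
            * (B + sl * b)
            / (a * b * (b * (B + sl * b) - a * (A + sl * a)))
        )
        return StabilityCondition(is_stabilising=lhs < rhs, lhs=lhs, rhs=rhs)

    def params_dict(self):
        d = {"TZr_kPa": self.TZr, "lambda_pre": self.lambda_pre, "S1": self.S1}
        if math.isfinite(self.lambda_hat_lb):
            d["lambda_hat_lb"] = self.lambda_hat_lb
        if math.isfinite(self.lambda_hat_ub):
            d["lambda_hat_ub"] = self.lambda_hat_ub
        return d


@dataclass(frozen=True)
class FranchiniModel(ActiveModel):
    """Polynomial force-length model (circumferential family only).

    ``t = S1 2 TFr1 lam_t^2 [1 + alpha1 E - beta1 E^m1]`` with
    ``E = lam_t^2 - 1``; dispersion and the axial family are fixed to zero.
    A closed-form Gamma_act exists for ``m1 = 2`` only.
    """

    TFr1: float
    alpha1: float
    beta1: float
    m1: int = 2
    S1: float = 1.0
    family = "franchini"

    def __post_init__(self):
        if self.TFr1 < 0.0:
            raise ValueError("TFr1 must be non-negative")
        if not (isinstance(self.m1, (int, np.integer)) and self.m1 >= 1):
            raise ValueError("m1 must be a positive integer")
        if not 0.0 <= self.S1 <= 1.0:
            raise ValueError("S1 must lie in [0, 1]")

    def cauchy_stress(self, lam_t):
        lam_t = np.asarray(lam_t, dtype=float)
        E = lam_t**2 - 1.0
        return (
            self.S1
            * 2.0
            * self.TFr1
            * lam_t**2
            * (1.0 + self.alpha1 * E - self.beta1 * E**self.m1)
        )

    def energy(self, lam_t):
        lam_t = np.asarray(lam_t, dtype=float)
        E = lam_t**2 - 1.0
        return self.S1 * self.TFr1 * (
            E + 0.5 * self.alpha1 * E**2 - self.beta1 / (self.m1 + 1.0) * E ** (self.m1 + 1)
        )

    def gamma_closed_form(self, geom, state):
        if self.m1 != 2:
            raise NoClosedFormError(
                f"franchini: closed form requires m1=2, got m1={self.m1}; "
                "use active_pressure_quadrature"
            )
        A, B, a, b, lz, _ = _geom_terms(geom, state)
        T1, al, be = self.TFr1, self.alpha1, self.beta1
        lnBA = math.log(B**2 / A**2)
        g = (
            T1 * (1.0 - al - be) / lz * lnBA
            + T1 * (al + 2.0 * be) / lz**2
            * (lnBA + (A**2 - a**2 * lz) * (A**2 - B**2) / (A**2 * B**2))
            - T1 * be / lz**3
            * (
                lnBA
                + (A**2 - a**2 * lz)
                / 2.0
                * ((3.0 * B**2 + b**2 * lz) / B**4 - (3.0 * A**2 + a**2 * lz) / A**4)
            )
        )
        return self.S1 * g

    def dgamma_da_closed_form(self, geom, state):
        if self.m1 != 2:
            raise NoClosedFormError("franchini: closed-form derivative requires m1=2")
        A, B, a, b, lz, _ = _geom_terms(geom, state)
        T1, al, be = self.TFr1, self.alpha1, self.beta1
        d = 2.0 * T1 * (al + 2.0 * be) * a * (B**2 - A**2) / (A**2 * B**2 * lz) - (
            2.0
            * T1
            * be
            * a
            * (B**4 * (A**2 + a**2 * lz) - A**4 * (B**2 + b**2 * lz))
            / (A**4 * B**4 * lz**2)
        )
        return self.S1 * d

    def stability(self, geom, state):
        if self.m1 != 2:
            return super().stability(geom, state)
        A, B, a, b, lz, _ = _geom_terms(geom, state)
        lhs = self.alpha1
        rhs = self.beta1 * (
            (B**4 * (A**2 + a**2 * lz) - A**4 * (B**2 + b**2 * lz))
            / (A**2 * B**2 * (B**2 - A**2) * lz)
            - 2.0
        )
        return StabilityCondition(is_stabilising=lhs > rhs, lhs=lhs, rhs=rhs)

    def params_dict(self):
        return {
            "TFr1_kPa": self.TFr1,
            "alpha1": self.alpha1,
            "beta1": self.beta1,
            "m1": int(self.m1),
            "S1": self.S1,
        }


def _lam_theta_breakpoints(geom, state, window):
    """Deformed radii where lam_theta(r) crosses the window boundaries."""
    b = deformed_outer_radius(geom, state)
    a, lz, A = state.a, state.lambda_z, geom.A
    pts = []
    for c in window:
        if not math.isfinite(c) or c <= 0.0:
            continue
        den = 1.0 - c**2 * lz
        if abs(den) < 1e-14:
            continue
        r2 = c**2 * (A**2 - a**2 * lz) / den
        if r2 <= 0.0:
            continue
        r = math.sqrt(r2)
        if a + 1e-12 < r < b - 1e-12:
            pts.append(r)
    return sorted(pts)


# ---------------------------------------------------------------------------
# functional facade
# ---------------------------------------------------------------------------

def active_cauchy_stress(model: ActiveModel, lam_t):
    """Circumferential active Cauchy stress t_act(lam_t) in kPa."""
    out = model.cauchy_stress(lam_t)
    return out if np.ndim(out) else float(out)


def active_energy(model: ActiveModel, lam_t):
    """Active energy Psi_act(lam_t) in kPa, zero at lam_t = 1 (gates permitting)."""
    out = model.energy(lam_t)
    return out if np.ndim(out) else float(out)


def active_pressure_closed_form(
    model: ActiveModel, geom: VesselGeometry, state: DeformationState
) -> float:
    """Closed-form Gamma_act; raises NoClosedFormError when not applicable."""
    return float(model.gamma_closed_form(geom, state))


def active_pressure_quadrature(
    model: ActiveModel, geom: VesselGeometry, state: DeformationState
) -> float:
    """Gamma_act by adaptive quadrature, split at stress on/off radii."""
    b = deformed_outer_radius(geom, state)
    a, lz, A = state.a, state.lambda_z, geom.A

    def integrand(r):
        R = math.sqrt((r**2 - a**2) * lz + A**2)
        return float(model.cauchy_stress(r / R)) / r

    pts = model._support_breakpoints(geom, state)
    val, _ = quad(integrand, a, b, points=pts or None, **_QUAD_KW)
    return float(val)


def active_pressure_derivative(
    model: ActiveModel, geom: VesselGeometry, state: DeformationState
) -> float:
    """d(Gamma_act)/da; analytic where printed, else central differences."""
    try:
        return float(model.dgamma_da_closed_form(geom, state))
    except NoClosedFormError:
        h = 1e-5 * max(state.a, 1.0)

        def g(aa):
            return active_pressure_quadrature(
                model, geom, DeformationState(aa, state.lambda_z)
            )

        return (g(state.a + h) - g(state.a - h)) / (2.0 * h)


def stability_condition(
    model: ActiveModel, geom: VesselGeometry, state: DeformationState
) -> StabilityCondition:
    """Evaluate the analytic stabilisation inequality where one exists."""
    return model.stability(geom, state)


# ---------------------------------------------------------------------------
# serialisation (JSON tagged unions)
# ---------------------------------------------------------------------------

_FAMILY_CLASSES = {
    "constant_cauchy": ConstantCauchyModel,
    "constant_1pk": ConstantFirstPKModel,
    "constant_2pk": ConstantSecondPKModel,
    "rachev": RachevModel,
    "zulliger": ZulligerModel,
    "franchini": FranchiniModel,
}

FAMILY_NAMES = tuple(_FAMILY_CLASSES)

_PARAM_KEYS = {
    "constant_cauchy": {"Tc_kPa": "Tc"},
    "constant_1pk": {"Ti_kPa": "Ti"},
    "constant_2pk": {"Tr_kPa": "Tr"},
    "rachev": {"TRv_kPa": "TRv", "lambda_m": "lambda_m", "lambda_0": "lambda_0"},
    "zulliger": {
        "TZr_kPa": "TZr",
        "lambda_pre": "lambda_pre",
        "S1": "S1",
        "lambda_hat_lb": "lambda_hat_lb",
        "lambda_hat_ub": "lambda_hat_ub",
    },
    "franchini": {
        "TFr1_kPa": "TFr1",
        "alpha1": "alpha1",
        "beta1": "beta1",
        "m1": "m1",
        "S1": "S1",
    },
}


def model_to_dict(model: ActiveModel) -> dict:
    return {"family": model.family, "params": model.params_dict()}


def model_from_dict(d: dict) -> ActiveModel:
    family = d["family"]
    if family not in _FAMILY_CLASSES:
        raise ValueError(f"unknown active model family {family!r}")
    keymap = _PARAM_KEYS[family]
    kwargs = {}
    for key, value in d.get("params", {}).items():
        if key not in keymap:
            raise ValueError(f"unknown parameter {key!r} for family {family!r}")
        kwargs[keymap[key]] = value
    if family == "franchini" and "m1" in kwargs:
        kwargs["m1"] = int(kwargs["m1"])
    return _FAMILY_CLASSES[family](**kwargs)
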