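"""Parameter estimation for the six active stress models.

Two regimes:

* ``fit_single_point`` — one contraction datum (held pressure, axial
  stretch, fractional outer-diameter reduction).  All model parameters
  except the stress-like one are imposed; the stress-like parameter is
  found by bounded scalar least squares on the modelled contracted outer
  diameter.  Because every family's active pressure is linear in its
  stress-like parameter, the unconstrained optimum has a direct solution;
  the fit then verifies it by quasi-static forward simulation (ramping the
  parameter from zero while tracking the equilibrium branch), which is what
  exposes fold instabilities: if the tracked branch snaps past the target
  diameter, no parameter value reproduces the measurement and the fit
  reports non-convergence with an instability flag.

* ``fit_active_curve`` — thin-wall active-pressure samples; bounded
  nonlinear least squares of sum((Gamma_exp - Gamma_mod)^2) with seeded
  Latin-hypercube multi-start for multi-parameter families and a discrete
  grid over the integer exponent of the polynomial force-length family.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy.optimize import brentq, least_squares
from scipy.stats import qmc

from .active_models import (
    ActiveModel,
    ConstantCauchyModel,
    ConstantFirstPKModel,
    ConstantSecondPKModel,
    FranchiniModel,
    RachevModel,
    ZulligerModel,
    active_cauchy_stress,
    active_pressure_quadrature,
)
from .inflation_solver import default_a_range, solve_radius, total_pressure
from .kinematics import (
    DeformationState,
    VesselGeometry,
    deformed_outer_radius,
    inner_radius_from_outer,
)
from .passive_wall import PassiveParams, passive_pressure
from .thinwall import ActivePressureSamples, ThinWallVessel, thinwall_active_pressure
from .units import to_kpa

__all__ = [
    "ContractionDatum",
    "FitResult",
    "fit_single_point",
    "fit_active_curve",
    "build_model",
    "stress_param_name",
    "imposed_preset",
    "active_stress_nonnull_over_range",
    "DEFAULT_MULTISTART_SEED",
]

DEFAULT_MULTISTART_SEED = 1234

#: stress-like (linear) parameter of each family
_STRESS_PARAM = {
    "constant_cauchy": "Tc",
    "constant_1pk": "Ti",
    "constant_2pk": "Tr",
    "rachev": "TRv",
    "zulliger": "TZr",
    "franchini": "TFr1",
}

_PRESETS = {
    # imposed (non-stress) parameters of the sparse-data mouse protocol
    "table1-mouse": {
        "constant_cauchy": {},
        "constant_1pk": {},
        "constant_2pk": {},
        "rachev": {"lambda_m": 1.60, "lambda_0": 0.80},
        "zulliger": {
            "lambda_pre": 1.83,
            "lambda_hat_lb": 1.20,
            "lambda_hat_ub": 3.83,
            "S1": 1.0,
        },
        "franchini": {"alpha1": 2.30, "beta1": 0.95, "m1": 2, "S1": 1.0},
    }
}


def stress_param_name(family: str) -> str:
    return _STRESS_PARAM[family]


def imposed_preset(name: str) -> Dict[str, dict]:
    """A named set of imposed (non-stress) parameters per model family."""
    return {k: dict(v) for k, v in _PRESETS[name].items()}


def build_model(family: str, stress_value: float, imposed: Optional[dict] = None) -> ActiveModel:
    """Construct a model from its family tag, stress-like value and imposed params."""
    imposed = dict(imposed or {})
    imposed[_STRESS_PARAM[family]] = stress_value
    cls = {
        "constant_cauchy": ConstantCauchyModel,
        "constant_1pk": ConstantFirstPKModel,
        "constant_2pk": ConstantSecondPKModel,
        "rachev": RachevModel,
        "zulliger": ZulligerModel,
        "franchini": FranchiniModel,
    }[family]
    return cls(**imposed)


@dataclass(frozen=True)
class ContractionDatum:
    """A single contraction measurement at held pressure and axial stretch."""

    pressure_mmHg: float
    lambda_z: float
    diameter_reduction: float  # fractional, e.g. 0.29

    def __post_init__(self) -> None:
        if self.pressure_mmHg <= 0.0:
            raise ValueError("held pressure must be positive")
        if not 0.0 <= self.diameter_reduction < 1.0:
            raise ValueError("diameter reduction must lie in [0, 1)")
        if self.lambda_z <= 0.0:
            raise ValueError("lambda_z must be positive")


@dataclass
class FitResult:
    """Estimated parameters plus convergence / stability diagnostics."""

    family: str
    parameters: Dict[str, float]
    residual: float
    converged: bool
    instability_flag: bool
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.residual < 0.0:
            raise ValueError("residual must be non-negative")

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "parameters": self.parameters,
            "residual": self.residual,
            "converged": self.converged,
            "instability_flag": self.instability_flag,
            "diagnostics": self.diagnostics,
        }


# ---------------------------------------------------------------------------
# single-point (sparse data) fit
# ---------------------------------------------------------------------------

class _PressureTable:
    """P(a; T) = Gamma_pas(a) + T * gamma_unit(a) tabulated on an a-grid.

    Exploits linearity of the active pressure in the stress-like parameter so
    that branch tracking over many T values costs two sweeps of quadrature.
    """

    def __init__(self, geom, passive_params, family, imposed, lambda_z, a_range, n=400):
        self.geom = geom
        self.passive = passive_params
        self.family = family
        self.imposed = imposed
        self.lambda_z = lambda_z
        self.a = np.linspace(a_range[0], a_range[1], n)
        unit_model = build_model(family, 1.0, imposed)
        self.gpas = np.array(
            [passive_pressure(geom, DeformationState(a, lambda_z), passive_params) for a in self.a]
        )
        self.gact = np.array(
            [
                active_pressure_quadrature(unit_model, geom, DeformationState(a, lambda_z))
                for a in self.a
            ]
        )

    def grid_roots(self, T: float, P_target: float) -> List[float]:
        """Approximate roots of P(a; T) = P_target by linear interpolation."""
        v = self.gpas + T * self.gact - P_target
        roots = []
        for j in range(len(self.a) - 1):
            if v[j] == 0.0:
                roots.append(self.a[j])
            elif v[j] * v[j + 1] < 0.0:
                w = v[j] / (v[j] - v[j + 1])
                roots.append(self.a[j] + w * (self.a[j + 1] - self.a[j]))
        if v[-1] == 0.0:
            roots.append(self.a[-1])
        return roots

    def track_branch(self, T_values, P_target: float, a_start: float):
        """Follow the equilibrium branch from ``a_start`` as T is ramped.

        Returns (radii along the branch, True if multiple roots were ever
        present).  A ``nan`` entry means the branch left the scanned range.
        """
        a_prev = a_start
        out = np.empty(len(T_values))
        multi = False
        for k, T in enumerate(T_values):
            roots = self.grid_roots(T, P_target)
            if len(roots) > 1:
                multi = True
            if not roots:
                out[k:] = np.nan
                break
            a_prev = min(roots, key=lambda r: abs(r - a_prev))
            out[k] = a_prev
        return out, multi


def fit_single_point(
    geom: VesselGeometry,
    passive_params: PassiveParams,
    datum: ContractionDatum,
    model_family: str,
    imposed_params: Optional[dict] = None,
    a_range: Optional[Tuple[float, float]] = None,
    n_scan: int = 400,
    n_ramp: int = 60,
) -> FitResult:
    """Fit the stress-like parameter of one family to a contraction datum.

    The relaxed configuration at the held pressure fixes the target outer
    diameter ``(1 - reduction) * b_relaxed``.  The stress parameter is bound
    below by zero; a target that the quasi-statically tracked branch cannot
    reach (fold/snap-through) yields ``converged=False`` with
    ``instability_flag=True`` rather than an exception.
    """
    P = to_kpa(datum.pressure_mmHg, "mmHg")
    lz = datum.lambda_z
    if a_range is None:
        a_range = default_a_range(geom)

    relaxed_roots = solve_radius(P, geom, lz, passive_params, None, a_range, n_scan)
    a_rel = relaxed_roots[-1]
    b_rel = deformed_outer_radius(geom, DeformationState(a_rel, lz))
    b_target = (1.0 - datum.diameter_reduction) * b_rel
    a_target = inner_radius_from_outer(geom, b_target, lz)

    name = _STRESS_PARAM[model_family]
    diag: dict = {"b_relaxed_mm": b_rel, "b_target_mm": b_target}

    if datum.diameter_reduction == 0.0:
        return FitResult(
            family=model_family,
            parameters={**(imposed_params or {}), name: 0.0},
            residual=0.0,
            converged=True,
            instability_flag=False,
            diagnostics=diag,
        )

    table = _PressureTable(
        geom, passive_params, model_family, imposed_params, lz, a_range, n_scan
    )
    st_target = DeformationState(a_target, lz)
    gamma_unit = active_pressure_quadrature(build_model(model_family, 1.0, imposed_params), geom, st_target)
    gamma_needed = P - passive_pressure(geom, st_target, passive_params)
    diag["gamma_needed_kPa"] = gamma_needed

    if gamma_unit <= 1e-12 or gamma_needed < 0.0:
        # the family cannot generate the required (positive) active pressure
        # at the target state, e.g. a gating window excluding the target
        return FitResult(
            family=model_family,
            parameters={**(imposed_params or {}), name: 0.0},
            residual=abs(b_target - b_rel),
            converged=False,
            instability_flag=False,
            diagnostics={**diag, "reason": "target not reachable with T >= 0"},
        )

    T_direct = gamma_needed / gamma_unit

    # quasi-static ramp 0 -> T_direct following the branch from the relaxed root
    Ts = np.linspace(0.0, T_direct, n_ramp)
    branch, multi = table.track_branch(Ts, P, a_rel)
    a_end = branch[-1]
    grid_step = table.a[1] - table.a[0]
    on_target = np.isfinite(a_end) and abs(a_end - a_target) < 3.0 * grid_step

    if on_target:
        # polish the equilibrium radius with the exact pressure function
        model = build_model(model_family, T_direct, imposed_params)

        def f(a):
            return total_pressure(geom, DeformationState(a, lz), passive_params, model) - P

        lo = max(a_target - 2 * grid_step, a_range[0])
        hi = min(a_target + 2 * grid_step, a_range[1])
        try:
            a_fit = brentq(f, lo, hi, xtol=1e-13)
        except ValueError:
            a_fit = a_target
        b_fit = deformed_outer_radius(geom, DeformationState(a_fit, lz))
        residual = abs(b_target - b_fit)
        return FitResult(
            family=model_family,
            parameters={**(imposed_params or {}), name: T_direct},
            residual=residual,
            converged=residual < 1e-6,
            instability_flag=multi,
            diagnostics={**diag, "branch_root_mm": a_fit, "ramp_steps": n_ramp},
        )

    # fold: the tracked branch snaps past the target. Minimise |b - b_target|
    # over the branch for T in [0, 2 T_direct].
    Ts = np.linspace(0.0, 2.0 * T_direct, 2 * n_ramp)
    branch, multi = table.track_branch(Ts, P, a_rel)
    b_branch = np.where(
        np.isfinite(branch),
        np.sqrt((geom.B**2 - geom.A**2) / lz + branch**2),
        np.nan,
    )
    resid = np.abs(b_branch - b_target)
    j = int(np.nanargmin(resid))
    return FitResult(
        family=model_family,
        parameters={**(imposed_params or {}), name: float(Ts[j])},
        residual=float(resid[j]),
        converged=False,
        instability_flag=True,
        diagnostics={
            **diag,
            "branch_root_mm": float(branch[j]),
            "reason": "target diameter unreachable on the tracked branch (fold)",
        },
    )


# ---------------------------------------------------------------------------
# thin-wall active-pressure curve fit
# ---------------------------------------------------------------------------

#: default bounds per free parameter (stress-like values in kPa)
_DEFAULT_BOUNDS = {
    "T": (0.0, 1e3),
    "lambda_m": (1.0 + 1e-6, 3.0),
    "rho0": (0.0, 0.99),  # lambda_0 = rho0 * lambda_m, keeps lambda_0 < lambda_m
    "lambda_pre": (0.5 + 1e-6, 3.0),
    "alpha1": (0.0, 5.0),
    "beta1": (0.0, 2.0),
}

_SHAPE_PARAMS = {
    "constant_cauchy": [],
    "constant_1pk": [],
    "constant_2pk": [],
    "rachev": ["lambda_m", "rho0"],
    "zulliger": ["lambda_pre"],
    "franchini": ["alpha1", "beta1"],
}


def _vector_to_model(family: str, x, names, imposed: dict, m1: int = 2) -> ActiveModel:
    vals = dict(imposed)
    vals.update(zip(names, x))
    T = vals.pop("T")
    if family == "rachev":
        lm = vals["lambda_m"]
        l0 = vals["lambda_0"] if "lambda_0" in vals else vals["rho0"] * lm
        return RachevModel(TRv=T, lambda_m=lm, lambda_0=l0)
    if family == "zulliger":
        return ZulligerModel(
            TZr=T,
            lambda_pre=vals["lambda_pre"],
            S1=vals.get("S1", 1.0),
            lambda_hat_lb=vals.get("lambda_hat_lb", -math.inf),
            lambda_hat_ub=vals.get("lambda_hat_ub", math.inf),
        )
    if family == "franchini":
        return FranchiniModel(
            TFr1=T, alpha1=vals["alpha1"], beta1=vals["beta1"], m1=m1,
            S1=vals.get("S1", 1.0),
        )
    return build_model(family, T)


def fit_active_curve(
    samples: ActivePressureSamples,
    vessel: ThinWallVessel,
    model_family: str,
    imposed_params: Optional[dict] = None,
    bounds: Optional[Dict[str, Tuple[float, float]]] = None,
    n_starts: int = 8,
    seed: int = DEFAULT_MULTISTART_SEED,
) -> FitResult:
    """Bounded nonlinear least squares of the thin-wall active pressure.

    Minimises sum((Gamma_exp - Gamma_mod)^2) over the family's free
    parameters (the stress-like parameter plus any shape parameters not
    fixed via ``imposed_params``).  Multi-parameter families use
    ``n_starts`` Latin-hypercube initial points (deterministic under
    ``seed``); the polynomial family's integer exponent is handled by a
    discrete grid over {1, 2, 3, 4} with a continuous inner solve.
    """
    d = samples.normalised_diameters
    g_exp = samples.gamma_act
    imposed = dict(imposed_params or {})
    names = ["T"] + [
        p
        for p in _SHAPE_PARAMS[model_family]
        if p not in imposed and not (p == "rho0" and "lambda_0" in imposed)
        and not (p == "lambda_m" and "lambda_m" in imposed)
    ]
    if d.size < len(names):
        raise ValueError("fewer samples than free parameters")
    if np.allclose(d, d[0]):
        raise ValueError("degenerate samples: all diameters equal")

    bnds = dict(_DEFAULT_BOUNDS)
    if bounds:
        bnds.update(bounds)
    lo = np.array([bnds[n][0] for n in names])
    hi = np.array([bnds[n][1] for n in names])

    if model_family == "franchini" and "m1" in imposed:
        m1_grid = (int(imposed.pop("m1")),)
    elif model_family == "franchini":
        m1_grid = (1, 2, 3, 4)
    else:
        m1_grid = (2,)

    def residuals(x, m1):
        model = _vector_to_model(model_family, x, names, imposed, m1=m1)
        return thinwall_active_pressure(model, vessel, d) - g_exp

    # initial points: mid-point plus Latin hypercube over the bounds
    starts = [0.5 * (lo + hi)]
    if len(names) > 1 and n_starts > 1:
        sampler = qmc.LatinHypercube(d=len(names), seed=seed)
        starts.extend(lo + sampler.random(n_starts - 1) * (hi - lo))

    best = None
    for m1 in m1_grid:
        for x0 in starts:
            sol = least_squares(residuals, x0, bounds=(lo, hi), args=(m1,), xtol=1e-14, ftol=1e-14, gtol=1e-14)
            cost = float(np.sum(sol.fun**2))
            if best is None or cost < best[0] - 1e-15:
                best = (cost, sol, m1)

    cost, sol, m1 = best
    model = _vector_to_model(model_family, sol.x, names, imposed, m1=m1)
    params = dict(model.params_dict())
    # rename *_kPa keys to bare names for FitResult readability
    params = { (k[:-4] if k.endswith("_kPa") else k): v for k, v in params.items() }
    hits = [n for n, v, l, h in zip(names, sol.x, lo, hi) if v <= l + 1e-12 or v >= h - 1e-12]
    jac = sol.jac
    cond = float(np.linalg.cond(jac)) if jac.size and np.all(np.isfinite(jac)) else math.inf
    return FitResult(
        family=model_family,
        parameters=params,
        residual=cost,
        converged=bool(sol.success),
        instability_flag=False,
        diagnostics={
            "n_starts": len(starts),
            "seed": seed,
            "bounds_hit": hits,
            "jacobian_condition": cond,
            "iterations": int(sol.nfev),
            "m1": int(m1) if model_family == "franchini" else None,
        },
    )


# ---------------------------------------------------------------------------
# auxiliary checker
# ---------------------------------------------------------------------------

def active_stress_nonnull_over_range(
    model: ActiveModel,
    geom: VesselGeometry,
    passive_params: PassiveParams,
    lambda_z: float,
    pressure_range_mmHg: Tuple[float, float] = (0.0, 200.0),
    n: int = 21,
) -> bool:
    """True if the active stress is non-null across the wall for every
    equilibrium configuration in the given pressure range.

    Used to audit imposed force-length support / gating windows: a window
    that switches the stress off inside the range introduces a kink in the
    pressure-diameter relation.
    """
    p_lo, p_hi = (to_kpa(p, "mmHg") for p in pressure_range_mmHg)
    a_range = default_a_range(geom)
    for P in np.linspace(max(p_lo, 1e-3), p_hi, n):
        try:
            roots = solve_radius(P, geom, lambda_z, passive_params, model, a_range)
        except Exception:
            return False
        a = roots[-1]
        st = DeformationState(a, lambda_z)
        b = deformed_outer_radius(geom, st)
        for lam_t in (a / geom.A, b / geom.B):
            if active_cauchy_stress(model, lam_t) <= 0.0:
                return False
    return True
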