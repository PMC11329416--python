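import math

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.optimize import brentq

from vasomech.active_models import (
    ConstantCauchyModel,
    ConstantFirstPKModel,
    ConstantSecondPKModel,
    FranchiniModel,
    NoClosedFormError,
    RachevModel,
    ZulligerModel,
    active_cauchy_stress,
    active_energy,
    active_pressure_closed_form,
    active_pressure_derivative,
    active_pressure_quadrature,
    model_from_dict,
    model_to_dict,
    stability_condition,
)
from vasomech.kinematics import DeformationState, VesselGeometry, deformed_outer_radius

from conftest import grid_states


class TestCauchyStress:
    def test_constant_models(self):
        assert active_cauchy_stress(ConstantCauchyModel(10.0), 1.7) == pytest.approx(10.0)
        assert active_cauchy_stress(ConstantFirstPKModel(10.0), 1.7) == pytest.approx(17.0)
        assert active_cauchy_stress(ConstantSecondPKModel(10.0), 1.7) == pytest.approx(
            10.0 * 1.7**2
        )

    def test_rachev_peak(self):
        m = RachevModel(TRv=67.2, lambda_m=1.6, lambda_0=0.8)
        assert active_cauchy_stress(m, 1.6) == pytest.approx(67.2 * 1.6)

    def test_rachev_outside_support(self):
        m = RachevModel(TRv=50.0, lambda_m=1.6, lambda_0=0.8)
        assert active_cauchy_stress(m, 0.5) == 0.0
        assert active_cauchy_stress(m, 2.5) == 0.0

    def test_zulliger_zero_crossing(self):
        m = ZulligerModel(TZr=45.3, lambda_pre=1.83)
        assert active_cauchy_stress(m, 1.0 / 1.83) == pytest.approx(0.0, abs=1e-12)

    def test_zulliger_gating(self):
        m = ZulligerModel(TZr=10.0, lambda_pre=1.0, lambda_hat_lb=1.1, lambda_hat_ub=1.5)
        assert active_cauchy_stress(m, 1.2) == pytest.approx(2.0)
        assert active_cauchy_stress(m, 1.6) == 0.0
        assert active_cauchy_stress(m, 1.05) == 0.0

    def test_franchini_at_unit_stretch(self):
        m = FranchiniModel(TFr1=7.0, alpha1=2.3, beta1=0.95, m1=2, S1=1.0)
        assert active_cauchy_stress(m, 1.0) == pytest.approx(14.0)


class TestActiveEnergy:
    def test_zero_at_unit_stretch(self, all_models):
        for name, model in all_models.items():
            if name == "zulliger":
                model = ZulligerModel(TZr=model.TZr, lambda_pre=1.0)
            assert active_energy(model, 1.0) == pytest.approx(0.0, abs=1e-12), name

    def test_constant_cauchy_log_form(self):
        assert active_energy(ConstantCauchyModel(2.0), math.e) == pytest.approx(2.0)

    @pytest.mark.parametrize("lam_t", [1.1, 1.3, 1.6, 1.9])
    def test_stress_is_energy_derivative(self, all_models, lam_t):
        """Oracle: t = 2 F dPsi/dC F = lam_t Psi'(lam_t) by central differences."""
        h = 1e-6
        for name, model in all_models.items():
            dpsi = (active_energy(model, lam_t + h) - active_energy(model, lam_t - h)) / (2 * h)
            assert active_cauchy_stress(model, lam_t) == pytest.approx(
                lam_t * dpsi, rel=1e-6
            ), name


class TestRachevForceLength:
    def test_endpoints_and_peak(self):
        m = RachevModel(TRv=1.0, lambda_m=1.6, lambda_0=0.8)
        assert m.force_length(0.8) == pytest.approx(0.0)
        assert m.force_length(1.6) == pytest.approx(1.0)
        assert m.force_length(2.4) == pytest.approx(0.0)

    def test_bounded_on_support(self):
        m = RachevModel(TRv=1.0, lambda_m=1.6, lambda_0=0.8)
        x = np.linspace(0.5, 2.8, 200)
        f = m.force_length(x)
        assert np.all(f >= 0.0)
        assert np.all(f <= 1.0)


class TestClosedForms:
    def test_second_pk_printed_value(self):
        # Tr=2, lz=1, B = e A: Gamma = (2/2) ln(e^2) = 2 for every a
        A = 0.7
        geom = VesselGeometry(A=A, B=math.e * A)
        m = ConstantSecondPKModel(2.0)
        for a in (0.5, 0.9, 1.5):
            st = DeformationState(a, 1.0)
            assert active_pressure_closed_form(m, geom, st) == pytest.approx(2.0)

    def test_identity_deformation_constant_models_coincide(self, geom):
        # at a=A, lz=1 all three stress measures coincide: Gamma = T ln(B/A)
        st = DeformationState(geom.A, 1.0)
        expected = 10.0 * math.log(geom.B / geom.A)
        for m in (ConstantCauchyModel(10.0), ConstantFirstPKModel(10.0), ConstantSecondPKModel(10.0)):
            assert active_pressure_closed_form(m, geom, st) == pytest.approx(expected, rel=1e-12)

    def test_closed_form_matches_quadrature_on_grid(self, geom, all_models):
        for name, model in all_models.items():
            for st in grid_states(geom, n_a=5, n_lz=4):
                cf = active_pressure_closed_form(model, geom, st)
                q = active_pressure_quadrature(model, geom, st)
                assert cf == pytest.approx(q, rel=1e-8, abs=1e-12), (name, st)

    def test_rachev_precondition_error(self, geom):
        m = RachevModel(TRv=50.0, lambda_m=1.6, lambda_0=1.4)  # narrow support
        st = DeformationState(1.2, 1.6)  # wall range [1.29, 1.5], support [1.4, 1.8]
        with pytest.raises(NoClosedFormError):
            active_pressure_closed_form(m, geom, st)

    def test_zulliger_precondition_error(self, geom):
        m = ZulligerModel(TZr=45.0, lambda_pre=1.83, lambda_hat_lb=2.5, lambda_hat_ub=2.6)
        st = DeformationState(1.2, 1.6)
        with pytest.raises(NoClosedFormError):
            active_pressure_closed_form(m, geom, st)

    def test_franchini_m1_not_2_error(self, geom, state):
        m = FranchiniModel(TFr1=10.0, alpha1=0.4, beta1=0.05, m1=3)
        with pytest.raises(NoClosedFormError):
            active_pressure_closed_form(m, geom, state)
        # quadrature still works
        assert active_pressure_quadrature(m, geom, state) > 0.0


class TestQuadrature:
    def test_zero_parameter(self, geom, state):
        for m in (ConstantCauchyModel(0.0), RachevModel(0.0, 1.6, 0.8)):
            assert active_pressure_quadrature(m, geom, state) == 0.0

    def test_rachev_partial_support_piecewise_oracle(self, geom):
        # wall range [1.29, 1.5]; support [1.4, 1.8] cuts the wall
        m = RachevModel(TRv=50.0, lambda_m=1.6, lambda_0=1.4)
        st = DeformationState(1.2, 1.6)
        b = deformed_outer_radius(geom, st)

        def lam_t(r):
            return r / math.sqrt((r**2 - st.a**2) * st.lambda_z + geom.A**2)

        # lam_t decreases with r here; find radius where lam_t = 1.4
        r_cut = brentq(lambda r: lam_t(r) - 1.4, st.a, b, xtol=1e-14)
        oracle, _ = quad(
            lambda r: float(m.cauchy_stress(lam_t(r))) / r, st.a, r_cut,
            epsabs=1e-13, epsrel=1e-12,
        )
        got = active_pressure_quadrature(m, geom, st)
        assert got == pytest.approx(oracle, rel=1e-9)

    def test_zulliger_gated_piecewise(self, geom):
        # gate cuts the wall: only part of it generates stress
        m_gated = ZulligerModel(TZr=45.0, lambda_pre=1.0, lambda_hat_lb=1.4, lambda_hat_ub=10.0)
        m_free = ZulligerModel(TZr=45.0, lambda_pre=1.0)
        st = DeformationState(1.2, 1.6)
        g_gated = active_pressure_quadrature(m_gated, geom, st)
        g_free = active_pressure_quadrature(m_free, geom, st)
        assert 0.0 < g_gated < g_free


class TestDerivatives:
    def test_constant_cauchy_printed_value(self):
        # Tc=1, a=1, b=2: dGamma/da = (1-4)/(1*4) = -0.75
        geom = VesselGeometry(A=1.0, B=2.0)
        st = DeformationState(1.0, 1.0)
        m = ConstantCauchyModel(1.0)
        assert active_pressure_derivative(m, geom, st) == pytest.approx(-0.75)
        # finite-difference oracle on Gamma
        h = 1e-6
        fd = (
            active_pressure_closed_form(m, geom, DeformationState(1.0 + h, 1.0))
            - active_pressure_closed_form(m, geom, DeformationState(1.0 - h, 1.0))
        ) / (2 * h)
        assert fd == pytest.approx(-0.75, rel=1e-8)

    def test_second_pk_identically_zero(self, geom):
        m = ConstantSecondPKModel(37.8)
        for st in grid_states(geom, n_a=6, n_lz=3):
            assert active_pressure_derivative(m, geom, st) == 0.0

    def test_constant_model_signs(self, geom):
        for st in grid_states(geom, n_a=6, n_lz=3):
            assert active_pressure_derivative(ConstantCauchyModel(10.0), geom, st) < 0.0
            assert active_pressure_derivative(ConstantFirstPKModel(10.0), geom, st) < 0.0

    def test_analytic_matches_central_differences(self, geom, all_models):
        h = 1e-6
        for name, model in all_models.items():
            for st in grid_states(geom, n_a=4, n_lz=3):
                fd = (
                    active_pressure_quadrature(model, geom, DeformationState(st.a + h, st.lambda_z))
                    - active_pressure_quadrature(model, geom, DeformationState(st.a - h, st.lambda_z))
                ) / (2 * h)
                an = active_pressure_derivative(model, geom, st)
                assert an == pytest.approx(fd, rel=5e-5, abs=1e-7), (name, st)


class TestStabilityConditions:
    def test_second_pk_neutral(self, geom, state):
        cond = stability_condition(ConstantSecondPKModel(100.0), geom, state)
        assert cond.is_stabilising is False
        assert active_pressure_derivative(ConstantSecondPKModel(100.0), geom, state) == 0.0

    def test_constant_cauchy_never_stabilising(self, geom):
        for st in grid_states(geom, n_a=5, n_lz=3):
            assert stability_condition(ConstantCauchyModel(50.0), geom, st).is_stabilising is False

    @pytest.mark.parametrize(
        "model",
        [
            RachevModel(TRv=67.2, lambda_m=1.6, lambda_0=0.4),
            ZulligerModel(TZr=45.3, lambda_pre=1.83),
            FranchiniModel(TFr1=12.5, alpha1=2.3, beta1=0.95, m1=2),
        ],
        ids=["rachev", "zulliger", "franchini"],
    )
    def test_inequality_crossover_matches_derivative_sign_change(self, geom, model):
        """The analytic inequality and the numeric derivative must change sign
        at the same inner radius (bisection oracle, 1e-4 mm)."""
        lz = 1.6

        def margin(a):
            c = stability_condition(model, geom, DeformationState(a, lz))
            return c.lhs - c.rhs if isinstance(model, (RachevModel, FranchiniModel)) else c.rhs - c.lhs

        def num_deriv(a):
            h = 1e-5
            return (
                active_pressure_quadrature(model, geom, DeformationState(a + h, lz))
                - active_pressure_quadrature(model, geom, DeformationState(a - h, lz))
            ) / (2 * h)

        a_lo, a_hi = 0.9 * geom.A, 1.9 * geom.A
        grid = np.linspace(a_lo, a_hi, 60)
        m_vals = np.array([margin(a) for a in grid])
        idx = np.nonzero(np.diff(np.sign(m_vals)))[0]
        assert len(idx) == 1, "expected exactly one crossover in the scanned range"
        j = idx[0]
        a_cond = brentq(margin, grid[j], grid[j + 1], xtol=1e-9)
        a_num = brentq(num_deriv, grid[j] - 0.02, grid[j + 1] + 0.02, xtol=1e-9)
        assert abs(a_cond - a_num) < 1e-4

    def test_condition_sign_agrees_with_derivative_everywhere(self, geom):
        models = [
            RachevModel(TRv=67.2, lambda_m=1.6, lambda_0=0.4),
            ZulligerModel(TZr=45.3, lambda_pre=1.83),
            FranchiniModel(TFr1=12.5, alpha1=2.3, beta1=0.95, m1=2),
        ]
        for model in models:
            for st in grid_states(geom, n_a=6, n_lz=3):
                cond = stability_condition(model, geom, st)
                d = active_pressure_derivative(model, geom, st)
                if abs(d) > 1e-10:
                    assert cond.is_stabilising == (d > 0.0), (model.family, st)


class TestDegeneracies:
    def test_zulliger_is_1pk_minus_cauchy(self, geom):
        TZr, lam_pre = 45.3, 1.83
        m = ZulligerModel(TZr=TZr, lambda_pre=lam_pre)
        m_1pk = ConstantFirstPKModel(TZr * lam_pre)
        m_c = ConstantCauchyModel(TZr)
        for st in grid_states(geom, n_a=4, n_lz=3):
            expected = active_pressure_closed_form(m_1pk, geom, st) - active_pressure_closed_form(
                m_c, geom, st
            )
            assert active_pressure_closed_form(m, geom, st) == pytest.approx(expected, rel=1e-12)
            assert active_pressure_quadrature(m, geom, st) == pytest.approx(expected, rel=1e-8)

    def test_franchini_degenerates_to_second_pk(self, geom):
        TFr1 = 12.5
        m = FranchiniModel(TFr1=TFr1, alpha1=0.0, beta1=0.0, m1=2, S1=1.0)
        m_2pk = ConstantSecondPKModel(2.0 * TFr1)
        for st in grid_states(geom, n_a=4, n_lz=3):
            assert active_pressure_closed_form(m, geom, st) == pytest.approx(
                active_pressure_closed_form(m_2pk, geom, st), rel=1e-10
            )
        x = np.linspace(0.7, 2.0, 9)
        np.testing.assert_allclose(m.cauchy_stress(x), m_2pk.cauchy_stress(x), rtol=1e-12)


class TestSerialisation:
    def test_roundtrip(self, all_models):
        for model in all_models.values():
            back = model_from_dict(model_to_dict(model))
            assert back == model

    def test_unknown_family(self):
        with pytest.raises(ValueError):
            model_from_dict({"family": "nope", "params": {}})

    def test_unknown_parameter(self):
        with pytest.raises(ValueError):
            model_from_dict({"family": "constant_cauchy", "params": {"bogus": 1.0}})


class TestValidation:
    def test_negative_stress_rejected(self):
        for cls, kwargs in [
            (ConstantCauchyModel, {"Tc": -1.0}),
            (ConstantFirstPKModel, {"Ti": -1.0}),
            (ConstantSecondPKModel, {"Tr": -1.0}),
        ]:
            with pytest.raises(ValueError):
                cls(**kwargs)

    def test_rachev_width(self):
        with pytest.raises(ValueError):
            RachevModel(TRv=1.0, lambda_m=1.0, lambda_0=1.5)

    def test_zulliger_bounds(self):
        with pytest.raises(ValueError):
            ZulligerModel(TZr=1.0, lambda_pre=1.0, S1=1.5)
        with pytest.raises(ValueError):
            ZulligerModel(TZr=1.0, lambda_pre=1.0, lambda_hat_lb=2.0, lambda_hat_ub=1.0)

    def test_franchini_m1(self):
        with pytest.raises(ValueError):
            FranchiniModel(TFr1=1.0, alpha1=0.0, beta1=0.0, m1=0)
        with pytest.raises(ValueError):
            FranchiniModel(TFr1=1.0, alpha1=0.0, beta1=0.0, m1=1.5)
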