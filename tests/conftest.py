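import numpy as np
import pytest

from vasomech.active_models import (
    ConstantCauchyModel,
    ConstantFirstPKModel,
    ConstantSecondPKModel,
    FranchiniModel,
    RachevModel,
    ZulligerModel,
)
from vasomech.kinematics import DeformationState, VesselGeometry
from vasomech.passive_wall import FibreFamily, PassiveParams


@pytest.fixture
def geom():
    """Simple unit-test geometry (mm)."""
    return VesselGeometry(A=0.8, B=1.0)


@pytest.fixture
def state():
    """Deformed state with wall stretch range [1.29, 1.5] on `geom`."""
    return DeformationState(a=1.2, lambda_z=1.6)


@pytest.fixture
def neo_hookean():
    return PassiveParams(mu=20.0)


@pytest.fixture
def four_fibre():
    return PassiveParams(
        mu=15.0,
        families=(
            FibreFamily(k1=8.0, k2=0.3, alpha_deg=0.0),
            FibreFamily(k1=5.0, k2=0.5, alpha_deg=90.0),
            FibreFamily(k1=3.0, k2=0.9, alpha_deg=45.0),
            FibreFamily(k1=3.0, k2=0.9, alpha_deg=-45.0),
        ),
    )


def _models():
    """Six representative models whose supports cover the test states."""
    return {
        "constant_cauchy": ConstantCauchyModel(Tc=47.3),
        "constant_1pk": ConstantFirstPKModel(Ti=42.1),
        "constant_2pk": ConstantSecondPKModel(Tr=37.8),
        "rachev": RachevModel(TRv=67.2, lambda_m=1.6, lambda_0=0.4),
        "zulliger": ZulligerModel(TZr=45.3, lambda_pre=1.83),
        "franchini": FranchiniModel(TFr1=12.5, alpha1=2.3, beta1=0.95, m1=2),
    }


@pytest.fixture(params=list(_models()))
def any_model(request):
    return _models()[request.param]


@pytest.fixture
def all_models():
    return _models()


@pytest.fixture
def mouse_fixture():
    from vasomech.fixtures import make_mouse_like_vessel

    return make_mouse_like_vessel()


def grid_states(geom, n_a=20, n_lz=20):
    """(a, lambda_z) grid keeping every wall stretch inside all model supports."""
    a_vals = np.linspace(0.9 * geom.A, 1.9 * geom.A, n_a)
    lz_vals = np.linspace(1.2, 1.8, n_lz)
    return [DeformationState(a, lz) for a in a_vals for lz in lz_vals]
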