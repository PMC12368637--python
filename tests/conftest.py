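import pytest

from bindkit.itc_onesite import OneSiteModel, TitrationProtocol
from bindkit.nmr_relaxation import FieldContext, ModelFreeParams


@pytest.fixture
def protocol() -> TitrationProtocol:
    """Standard overflow-cell titration: 200 uL cell, 30 uM macromolecule,
    300 uM titrant, one 0.4 uL pre-injection then 14 x 3 uL, 298.35 K."""
    return TitrationProtocol()


@pytest.fixture
def hsa_hcc_model() -> OneSiteModel:
    """Fitted one-site parameters of the weak albumin-cystatin interaction."""
    return OneSiteModel(n=0.642, kd_m=1.15e-6, dh_kcal_mol=1.88)


@pytest.fixture
def field_188() -> FieldContext:
    return FieldContext(b0_t=18.8)


@pytest.fixture
def field_117() -> FieldContext:
    return FieldContext(b0_t=11.7)


@pytest.fixture
def rigid_params() -> ModelFreeParams:
    return ModelFreeParams(tau_r_s=7.45e-9, s2=0.85, tau_e_s=20e-12)
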