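import pytest
from hypothesis import settings as _hypothesis_settings

from thermogrowth.fit import registry_with_gains

_hypothesis_settings.register_profile("deterministic", derandomize=True,
                                      deadline=None)
_hypothesis_settings.load_profile("deterministic")
from thermogrowth.model import ParameterSet
from thermogrowth.synth import reference_parameters


@pytest.fixture(scope="session")
def ref():
    """Packaged reference parameters and fitted genotype gains."""
    return reference_parameters()


@pytest.fixture(scope="session")
def ref_params(ref):
    return ref[0]


@pytest.fixture(scope="session")
def ref_registry(ref):
    return registry_with_gains(ref[1])


@pytest.fixture()
def simple_params():
    """Round-numbered parameter set for arithmetic-level checks."""
    return ParameterSet(
        k_pB=1.0, k_rB=0.5, k_dB=0.1, Q10_B=2.0,
        a_E=0.4, d_E=0.3, b_E=0.2, w_E=4.0, rho_E=0.05,
        C_dark=1.0, C_light=0.2, eps_C=0.2, tau_C=1.0,
        a_P=1.0, K_E=0.5, h_E=2.0, d_P=0.5, beta_B=4.0, beta_C=3.0,
        Y0=1.0, K_C=0.5,
        v0=0.01, v_max=0.1, K_G=1.0, n_G=2.0, K_Bg=0.5, K_Eg=1.0, K_Yg=1.0,
        H0=0.5)
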