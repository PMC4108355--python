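import pytest

from loopburst.params import RateParameters, uninduced_parameters
from loopburst.reduction import DimensionlessParameters


@pytest.fixture(scope="session")
def uninduced() -> RateParameters:
    """Packaged uninduced parameter set (consistency-checked on load)."""
    return uninduced_parameters()


@pytest.fixture(scope="session")
def uninduced_noaux(uninduced) -> RateParameters:
    return uninduced.without_aux()


@pytest.fixture()
def small_fast_params() -> RateParameters:
    """A down-scaled parameter set with O(1) propensities, cheap to simulate
    exactly (no timescale separation is assumed by the exact oracles)."""
    return RateParameters(
        k_a=0.3, k_d1=0.2, k_d2=0.4, k_d3=0.6, kl_12=1.0, kl_13=1.5,
        nu=1.0, g_m=1.0, k_p=0.5, g_p=0.1,
    )


def random_dimensionless(rng, phi_zero=False) -> DimensionlessParameters:
    """Small random parameter set in the fast-mRNA regime (a <= 50, b <= 5,
    gamma large so the adiabatic solution is near-exact)."""
    a = rng.uniform(5, 50)
    b = rng.uniform(0.5, 4.0)
    kf = rng.uniform(0.2, 3.0)
    kb = rng.uniform(2.0, 60.0)
    phi = 0.0 if phi_zero else rng.uniform(0.0, 0.01)
    return DimensionlessParameters(a=a, b=b, gamma=1500.0, kf=kf, kb=kb,
                                   phi_bound=phi)
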