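import logging

import pytest

from coevodyn import HostParams, ParasitoidParams, SimConfig

# Character-evolution clamp warnings are expected noise in stress tests.
logging.getLogger("coevodyn").setLevel(logging.ERROR)


@pytest.fixture
def lb_host() -> HostParams:
    """Argentine stem weevil host at its tabulated values (lambda pinned
    mid-range at 10 for oracle arithmetic)."""
    return HostParams(lambda_star=10.0, K=720.0, C_n=1.0, Gamma_n=0.01,
                      N0=720.0, n0=1.0)


@pytest.fixture
def lb_parasitoid() -> ParasitoidParams:
    """Its parasitoid at tabulated values (kappa pinned at 0.5)."""
    return ParasitoidParams(eta_star=42.0, c=0.92, a=4.14, kappa=0.5,
                            C_p=1.0, Gamma_p=0.0, P0=10.0, p0=0.9)


@pytest.fixture
def config() -> SimConfig:
    return SimConfig(generations=300)
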