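import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from ephysgan import datasets as D
from ephysgan import model as M

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_params():
    return M.default_parameters()


@pytest.fixture(scope="session")
def dep_protocol():
    return M.depolarizing_protocol()


@pytest.fixture(scope="session")
def hyp_protocol():
    return M.hyperpolarizing_protocol()


@pytest.fixture(scope="session")
def default_traces(default_params, dep_protocol, hyp_protocol):
    """One depolarizing and one hyperpolarizing trace of the default cell."""
    t, Vd, sd = M.simulate_batch([default_params], dep_protocol)
    th, Vh, sh = M.simulate_batch([default_params], hyp_protocol, dt=0.05)
    assert sd[0] == 0 and sh[0] == 0
    return (M.VoltageTrace(t, Vd[0], dep_protocol),
            M.VoltageTrace(th, Vh[0], hyp_protocol))


@pytest.fixture(scope="session")
def small_dataset():
    """An 80-row uniform sweep shared by feature-range / GAN / MCMC tests."""
    return D.make_training_dataset(80, seed=7)


def leak_only_params(g_L=0.06, E_L=-70.0, C=1.0):
    base = M.default_parameters()
    return base.replace(g_NaT=0.0, g_NaP=0.0, g_CaT=0.0, g_CaH=0.0,
                        g_KDR=0.0, g_KM=0.0, g_H=0.0, g_L=g_L, E_L=E_L, C=C)


@pytest.fixture(scope="session")
def leak_params():
    return leak_only_params()
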