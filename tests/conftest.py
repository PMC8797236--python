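import numpy as np
import pytest

from ictalwave.params import HazardParams, default_E_population, default_I_population


@pytest.fixture
def hz_E():
    return HazardParams(g_L=default_E_population().g_L, V_th_base=-50.0)


@pytest.fixture
def pop_E():
    return default_E_population()


@pytest.fixture
def pop_I():
    return default_I_population()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
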