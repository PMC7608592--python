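import numpy as np
import pytest

from pgmkin import presets, synth
from pgmkin.rate_law import KineticParameters


@pytest.fixture
def wt_params():
    return presets.WT_PARAMS


@pytest.fixture
def p146a_params():
    return presets.P146A_PARAMS


@pytest.fixture
def wt_table():
    """Noiseless initial-rate grid on the wild-type concentration lists."""
    return synth.gen_rate_table(presets.WT_PARAMS)


@pytest.fixture
def p146a_table():
    return synth.gen_rate_table(
        presets.P146A_PARAMS,
        bG1P_list=presets.P146A_BG1P_GRID_UM,
        bG16BP_list=presets.P146A_BG16BP_GRID_UM,
        E_T=presets.P146A_ET_UM,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_params(rng) -> KineticParameters:
    """Log-uniform random parameter vector for property sweeps."""
    draw = lambda lo, hi: float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    return KineticParameters(
        k_cat=draw(0.1, 1e4),
        K_bG1P=draw(0.5, 5e3),
        K_bG16BP=draw(0.5, 5e3),
        K_i=draw(10.0, 1e5),
    )
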