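import numpy as np
import pytest

from macscreen.synthetic_data import CompoundEffect, CytonParams


@pytest.fixture
def params():
    """Default study-condition kinetics at a reduced founder count."""
    return CytonParams(n0=500)


@pytest.fixture
def identity():
    return CompoundEffect()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def cohort_total(state):
    """Division-corrected total: sum of N_i / 2**i."""
    weights = 2.0 ** np.arange(state.max_gen + 1)
    return float((state.census() / weights).sum())
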