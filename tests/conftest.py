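import numpy as np
import pytest

from gfnet import PopulationConfig, build_input_population
from gfnet.recipes import make_fixture


@pytest.fixture(scope="session")
def small_peaked_pop():
    cfg = PopulationConfig(
        gain_form="peaked",
        retinal_span=(-40.0, 40.0), retinal_step=4.0,
        eye_span=(-18.0, 18.0), eye_step=6.0,
    )
    return build_input_population(cfg, seed=1)


@pytest.fixture(scope="session")
def small_sigmoid_pop():
    cfg = PopulationConfig(
        gain_form="sigmoid",
        retinal_span=(-40.0, 40.0), retinal_step=4.0,
        eye_span=(-18.0, 18.0), eye_step=6.0,
    )
    return build_input_population(cfg, seed=1)


@pytest.fixture()
def fixture_config():
    return make_fixture(seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
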