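import numpy as np
import pytest

from hydromix.core import Box
from hydromix import synth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def water_tmpl():
    return synth.water_template()


@pytest.fixture(scope="session")
def thal_tmpl():
    return synth.pseudo_trehalose_template()


@pytest.fixture(scope="session")
def hydrated_traj():
    """3 pseudo-trehalose molecules, 2 donor waters on each hydroxyl site."""
    return synth.generate_hydrated_trehalose(
        3, waters_per_site=2, d_hb=2.8, box=Box((60.0, 60.0, 60.0)), seed=11)


@pytest.fixture(scope="session")
def small_gas_traj():
    """Mixed water/trehalose gas for oracle comparisons."""
    return synth.generate_gas_configuration(
        {"WATER": 40, "THAL": 6}, Box((32.0, 32.0, 32.0)), seed=7,
        min_distance=2.0)
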