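import numpy as np
import pytest

from neuromass.brain_network import Atlas, Region
from neuromass.synthetic_scenarios import ScenarioSpec, make_synthetic_connectivity, make_synthetic_head


@pytest.fixture(scope="session")
def small_head():
    """8 cortical regions + thalamus: fast enough for network unit tests."""
    spec = ScenarioSpec(n_regions=8)
    atlas, electrodes, leadfield = make_synthetic_head(spec)
    conn = make_synthetic_connectivity(atlas, spec.conn_decay_mm, 0.5, seed=1)
    return atlas, electrodes, leadfield, conn


@pytest.fixture(scope="session")
def default_head():
    spec = ScenarioSpec()
    return make_synthetic_head(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def toy_atlas():
    """Hand-built 4-region cortical atlas + thalamus with round coordinates."""
    return Atlas(
        (
            Region("lh.a", "lh", (-40.0, 50.0, 20.0)),
            Region("lh.b", "lh", (-50.0, -10.0, 40.0)),
            Region("rh.a", "rh", (40.0, 50.0, 20.0)),
            Region("rh.b", "rh", (50.0, -10.0, 40.0)),
            Region("thalamus", "sub", (0.0, -10.0, 10.0)),
        )
    )
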