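import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from demewar import ModelParams, PopulationState, TopologyKind, TopologySpec, validate_params


def state_from(strategies, fitness, generation=0) -> PopulationState:
    """Build a state from per-deme python lists."""
    return PopulationState(
        generation=generation,
        strategies=[np.asarray(s, dtype=np.int8) for s in strategies],
        fitness=[np.asarray(f, dtype=np.float64) for f in fitness],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def island_spec():
    return TopologySpec(kind=TopologyKind.ISLAND)


@pytest.fixture
def small_params(island_spec):
    """A tiny, fast parameterisation: 5 demes of 6 on the island network."""
    return validate_params(
        ModelParams(N=30, D=5, m=0.3, topology=island_spec, seed=7)
    )
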