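import numpy as np
import pytest

from sanctum.core import SimParams, TypeParams
from sanctum.graphs import MetapopGraph, NodeSpec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def selective_params():
    """Calibrated two-type parameters: mutant holds a ~20% growth edge."""
    return SimParams(
        wild=TypeParams(birth_rate=1.0, kill_rate=1.5),
        mutant=TypeParams(birth_rate=1.0, kill_rate=1.0),
        antibiotic=0.25,
        founders=0,
        founder_mutants=0,
    )


@pytest.fixture
def neutral_params():
    """Identical demographic parameters for both types."""
    return SimParams(
        wild=TypeParams(birth_rate=1.0, kill_rate=1.0),
        mutant=TypeParams(birth_rate=1.0, kill_rate=1.0),
        antibiotic=0.25,
        founders=0,
        founder_mutants=0,
    )


def single_node(capacity: int) -> MetapopGraph:
    return MetapopGraph([NodeSpec("P1", capacity)], [])


@pytest.fixture
def single_node_graph():
    return single_node
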