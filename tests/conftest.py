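import numpy as np
import pytest

from numlot import ApproxConfig, FrequencyVector, LoTParams


@pytest.fixture
def unit_params():
    """Unit costs, f1 = 0.1: the hand-checkable toy grammar."""
    return LoTParams(f1=0.1, cost_add=1.0, cost_mult=1.0)


@pytest.fixture
def realistic_params():
    """Parameters whose cumulative output has the canonical ~1/n^2 shape."""
    from numlot.synthetic_data import DEFAULT_TRUE_PARAMS

    return DEFAULT_TRUE_PARAMS


@pytest.fixture
def approx_config():
    from numlot.synthetic_data import DEFAULT_APPROX

    return DEFAULT_APPROX


def random_params(rng) -> LoTParams:
    """Log-uniform parameter draw: f1 in [1e-3, 10], costs in [1e-3, 1]."""
    return LoTParams(
        f1=10.0 ** rng.uniform(-3, 1),
        cost_add=10.0 ** rng.uniform(-3, 0),
        cost_mult=10.0 ** rng.uniform(-3, 0),
    )


def random_freq_vector(rng, n_max=99) -> FrequencyVector:
    return FrequencyVector(10.0 ** rng.uniform(-3, 3, size=n_max))
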