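import numpy as np
import pytest

from qcoevo import PayoffParams, classical_C, classical_D, random_strategy


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def payoffs_b2():
    return PayoffParams.from_temptation(2.0)


@pytest.fixture
def four_strategies(rng):
    """A run's strategy set: C, D and two random quantum draws."""
    return [
        classical_C(),
        classical_D(),
        random_strategy(rng, label="QA"),
        random_strategy(rng, label="QB"),
    ]
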