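import numpy as np
import pytest

from beefield.permutation import PairedTrial


def make_pairs(controls, treatments):
    return [
        PairedTrial(i, int(t), int(c))
        for i, (t, c) in enumerate(zip(treatments, controls))
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(20231)


@pytest.fixture
def poisson_pairs(rng):
    """Eight Poisson(12) treatment/control pairs, a realistic study shape."""
    c = rng.poisson(12, size=8)
    t = rng.poisson(12, size=8)
    return make_pairs(c, t)
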