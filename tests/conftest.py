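import random

import pytest

from groupsigma.kernels import ModelParams, range_pattern


@pytest.fixture
def params_small() -> ModelParams:
    """A tiny population for which the exact chain is cheap to enumerate."""
    return ModelParams(N=3, M=2, u=0.5, v=0.5)


@pytest.fixture
def rng() -> random.Random:
    return random.Random(20160524)


def random_params(rnd: random.Random, n_min: int = 3, n_max: int = 400) -> ModelParams:
    """A random valid parameter set with strictly positive u and v."""
    return ModelParams(
        N=rnd.randint(n_min, n_max),
        M=rnd.randint(2, 40),
        u=rnd.uniform(1e-3, 1.0),
        v=rnd.uniform(1e-3, 1.0),
    )
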