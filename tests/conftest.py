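import numpy as np
import pytest

from somnokit import DesignMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20230303)


def make_null_design(rng, n_per_group=(5, 5), n_times=6, sd=1.0):
    """Balanced-in-time design with no group effect: shared subject and
    time structure plus noise."""
    n = sum(n_per_group)
    subj = rng.normal(0.0, 1.0, size=(n, 1))
    time = rng.normal(0.0, 1.0, size=(1, n_times))
    values = 10.0 + subj + time + rng.normal(0.0, sd, size=(n, n_times))
    groups = np.repeat(["a", "b"], n_per_group)
    return DesignMatrix(values=values, groups=groups)


@pytest.fixture
def null_design_factory():
    return make_null_design
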