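import numpy as np
import pytest

from xciskew import QuantSample
from xciskew.simulate import SimScenario, simulate_sample


@pytest.fixture
def toy_sample():
    """Six females, two per genotype, unit within-group variances.

    Group means (1, 2, 3) give beta = (1, 1, 1) and gamma = 1 exactly.
    """
    return QuantSample([0, 2, 1, 3, 2, 4], [0, 0, 1, 1, 2, 2])


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def make_sample(rng, n=600, p=0.3, gamma=1.2, a=0.3, **kw):
    """One simulated sample under the generative model (resampled if a
    genotype group would be too small to fit)."""
    scen = SimScenario(p=p, gamma=gamma, a=a, n=n, **kw)
    while True:
        s = simulate_sample(scen, rng)
        if s.group_counts().min() >= 3:
            return s


@pytest.fixture
def sim_sample(rng):
    return make_sample(rng)
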