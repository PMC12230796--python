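import numpy as np
import pytest

from tetrack import simulate as sim


@pytest.fixture(scope="session")
def family():
    """A 3 kb TE family with an 8%-diverged degraded ancestor."""
    return sim.TEFamily.generate("te1", 3000, 0.08, np.random.default_rng(42))


@pytest.fixture(scope="session")
def genes():
    return sim.make_single_copy_genes(seed=77)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
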