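import numpy as np
import pytest

from barrierbo import LandscapeSpec, generate


@pytest.fixture(scope="session")
def tiny():
    """2 sites x 3 substituents (9 substrates): fast structural checks."""
    spec = LandscapeSpec(n_sites=2, n_substituents=3, seed=7)
    table, landscape = generate(spec)
    return spec, table, landscape


@pytest.fixture(scope="session")
def small():
    """3 sites x 5 substituents (125 substrates): full-budget loop checks."""
    spec = LandscapeSpec(n_sites=3, n_substituents=5, seed=11)
    table, landscape = generate(spec)
    return spec, table, landscape


@pytest.fixture
def rng():
    return np.random.default_rng(42)
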