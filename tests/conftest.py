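import numpy as np
import pytest

from ribocirc import simdata


@pytest.fixture(scope="session")
def default_bundle():
    """One shared synthetic dataset (defaults: 5 translated, 5 untranslated,
    8 junction reads each, contaminants and adapters on)."""
    return simdata.simulate_dataset(simdata.SimConfig(seed=0))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
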