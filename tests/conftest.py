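import numpy as np
import pytest

from flowcall.priors import default_priors


@pytest.fixture(scope="session")
def priors():
    """The shipped default parameter table (read-only across tests)."""
    return default_priors()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
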