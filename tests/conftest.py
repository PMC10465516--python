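import numpy as np
import pytest

from fissureintegrity.phantom import PhantomSpec, generate_case


@pytest.fixture(scope="session")
def default_case():
    """One default phantom case shared (read-only) across tests."""
    return generate_case(PhantomSpec(seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
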