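import numpy as np
import pytest

from truenet.phantom import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def default_case():
    """One default anisotropic phantom case (shared, read-only)."""
    return generate_phantom(PhantomSpec(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
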