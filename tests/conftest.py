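import numpy as np
import pytest

from sedimine import simulate


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture(scope="session")
def library():
    return simulate.reference_compound_library()


@pytest.fixture(scope="session")
def library_by_name(library):
    return {c.name: c for c in library}
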