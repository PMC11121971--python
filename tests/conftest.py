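import numpy as np
import pytest

from oligodeg.fixtures import load_fixtures


@pytest.fixture(scope="session")
def paper():
    """The packaged reference tables (checksum-verified)."""
    return load_fixtures()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240516)
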