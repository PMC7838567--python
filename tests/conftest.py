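import numpy as np
import pytest

from tsrkeys import BinScheme, LabelTable
from tsrkeys.discretize import default_scheme


@pytest.fixture(scope="session")
def scheme() -> BinScheme:
    """The shipped 29/35 default scheme."""
    return default_scheme()


@pytest.fixture(scope="session")
def small_scheme() -> BinScheme:
    """A tiny scheme for exhaustive digit-space checks."""
    return BinScheme(
        theta_boundaries=(20.0, 45.0, 70.0),
        maxdist_boundaries=(5.0, 10.0),
        m=5,
    )


@pytest.fixture(scope="session")
def label_table() -> LabelTable:
    return LabelTable.default()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20210113)
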