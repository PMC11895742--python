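import numpy as np
import pytest

from stratext.column import StratColumn, column_from_thicknesses
from stratext.synthetic_data import fixture_mini_meishan


@pytest.fixture(scope="session")
def mini():
    """The deterministic 12-bed / 40-taxon / 4-proxy bundled section."""
    return fixture_mini_meishan()


@pytest.fixture()
def column10() -> StratColumn:
    """Ten half-metre beds labelled 1..10 starting at 0 m."""
    return column_from_thicknesses([str(i) for i in range(1, 11)], [0.5] * 10)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
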