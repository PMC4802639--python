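import numpy as np
import pytest
from hypothesis import settings

from hbnspec import fixtures as fx
from hbnspec.regression import ModelSource

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=100)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def amber_records():
    """The five geometry-optimised (AMBER) pigment records."""
    return [r for r in fx.load_table1() if r.model_source == ModelSource.AMBER]


@pytest.fixture(scope="session")
def table2():
    return fx.load_table2()


@pytest.fixture(scope="session")
def table3():
    return fx.load_table3()


@pytest.fixture(scope="session")
def table3_frame():
    return fx.load_table3_frame()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260923)
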