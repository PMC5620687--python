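import numpy as np
import pytest

from biopra import builtin_dataset


@pytest.fixture(scope="session")
def table4():
    return builtin_dataset("table4_apparent")


@pytest.fixture(scope="session")
def table5():
    return builtin_dataset("table5_marginal")


@pytest.fixture(scope="session")
def trathala_apparent(table4):
    """The 25 apparent-mortality values for T. flavoorbitalis."""
    return table4.rates("tflavoorbitalis")


@pytest.fixture(scope="session")
def trathala_marginal(table5):
    """The 18 marginal attack rates for T. flavoorbitalis."""
    return table5.rates("tflavoorbitalis")


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
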