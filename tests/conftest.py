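import numpy as np
import pytest

from ampedit.reference import build_reference
from ampedit.profiling import build_recoding_table


@pytest.fixture(scope="session")
def ref():
    return build_reference()


@pytest.fixture(scope="session")
def recoding(ref):
    return build_recoding_table(ref)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def q(values):
    """Shorthand: quality array from a list of ints."""
    return np.asarray(values, dtype=np.int16)
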