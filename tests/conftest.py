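import numpy as np
import pytest

from modshift import build_reference
from modshift.synthetic_spectra import P53_SEQUENCE


@pytest.fixture(scope="session")
def p53_ref():
    """Reference model of full-length human p53 (~43.65 kDa)."""
    return build_reference(P53_SEQUENCE)


@pytest.fixture(scope="session")
def small_ref():
    """A ~14 kDa reference protein (the smallest size the sliding-window
    test is designed for)."""
    return build_reference(P53_SEQUENCE[:127])


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
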