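import numpy as np
import pytest

from prefilt._util import substream
from prefilt.synthetic import generate_stimuli


@pytest.fixture(scope="session")
def small_set():
    """12 synthetic stimuli/mask pairs at 64 px (shared, read-only)."""
    return generate_stimuli(12, 64, seed=7)


@pytest.fixture(scope="session")
def medium_set():
    """30 synthetic stimuli/mask pairs at 64 px (shared, read-only)."""
    return generate_stimuli(30, 64, seed=11)


@pytest.fixture()
def rng():
    return substream(123, "tests")
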