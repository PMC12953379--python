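import numpy as np
import pytest

from cardiosleep.synthetic import (default_hypnogram_params,
                                   default_physio_params)


@pytest.fixture(scope="session")
def hyp_params():
    return default_hypnogram_params(seed=0)


@pytest.fixture(scope="session")
def physio_params():
    return default_physio_params(seed=0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
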