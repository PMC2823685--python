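import pytest

import regulonkit as rk


@pytest.fixture(scope="session")
def zur_model():
    """Palindromic PWM from the five published 21-bp operator sites, thresholded."""
    return rk.default_zur_model()


@pytest.fixture(scope="session")
def table1_fixture():
    """Single genome reproducing the published regulon geometry, plus truth."""
    return rk.table1_layout(seed=0)


@pytest.fixture(scope="session")
def direct_targets():
    return rk.load_direct_targets()


@pytest.fixture(scope="session")
def secondary_targets():
    return rk.load_secondary_targets()
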