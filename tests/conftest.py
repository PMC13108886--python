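import numpy as np
import pytest

from pombesig.synthetic import default_truth


@pytest.fixture(scope="session")
def truth():
    """Packaged ground truth with its noiseless panel (computed once)."""
    return default_truth()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
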