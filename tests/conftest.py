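import numpy as np
import pytest

from mirmeta import focal_mirna_record


@pytest.fixture(scope="session")
def mir203():
    return focal_mirna_record()


@pytest.fixture()
def rng():
    return np.random.default_rng(20150723)
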