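import numpy as np
import pytest

from kcsalink import synth


@pytest.fixture
def wt_scheme():
    """Wild-type-like three-state gating scheme (I <-> P <-> C)."""
    return synth.GatingScheme.three_state()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
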