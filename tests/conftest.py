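import numpy as np
import pytest

from fbt.synth import HeadModel


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def head_model():
    """Symmetric-head model with the default calibration."""
    return HeadModel()
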