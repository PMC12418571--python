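import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20250926)


@pytest.fixture
def shift_series():
    """Reference volume plus the six ground-truth single-axis shifts."""
    from vvoqc import pure_shift_series

    return pure_shift_series()
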