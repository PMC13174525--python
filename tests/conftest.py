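import warnings

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("suite")


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture(autouse=True)
def _no_subvoxel_warnings():
    # sub-voxel fiber warnings are exercised explicitly in one test
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="fiber radius .* is sub-voxel")
        yield
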