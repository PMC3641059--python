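import numpy as np
import pytest

from pictools import PipelineConfig, SimFieldConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_field_config():
    """A fast 128x128 field with few cells for unit tests."""
    return SimFieldConfig(field_shape=(128, 128), n_cells=4, seed=11)


@pytest.fixture
def params():
    return PipelineConfig()
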