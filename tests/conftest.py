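import numpy as np
import pytest

from gemsort import SynthConfig, render_recording


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def short_recording():
    """A 10 s default-parameter recording shared by detection-level tests."""
    cfg = SynthConfig(duration_s=10.0, seed=7)
    block, truth = render_recording(cfg)
    return cfg, block, truth
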