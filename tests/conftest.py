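import numpy as np
import pytest

from bscn.synthetic import SynthParams, generate_scene


@pytest.fixture(scope="session")
def default_scene():
    """One deterministic mid-size scene shared across read-only tests."""
    return generate_scene(SynthParams(image_size=(128, 128), seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
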