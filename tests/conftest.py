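import numpy as np
import pytest

from vitalmag.synthetic_scenes import SceneSpec, generate_breathing_video


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def short_blob_scene():
    """30 s breathing blob at 10 fps: delta0=0.05 px at 0.25 Hz (noiseless)."""
    spec = SceneSpec(duration=30.0)
    video, truth = generate_breathing_video(spec)
    return spec, video, truth
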