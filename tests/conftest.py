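import numpy as np
import pytest

from sowmorph.geometry import Intrinsics
from sowmorph.synthetic import SceneSpec, SowShapeParams, generate_scene

# Half-resolution intrinsics used by the heavier fixtures (same field of
# view as the 400x240 sensor, quarter the pixels).
HALF_RES = Intrinsics(fx=107.9673, fy=107.9673, width=200, height=120)


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


@pytest.fixture(scope="session")
def noiseless_sample():
    """One exact scene: default shape, no noise, no dropout."""
    return generate_scene(SceneSpec(noise_sd=0.0, dropout_rate=0.0))


@pytest.fixture(scope="session")
def small_sample():
    """Cheap half-resolution scene with noise, for pipeline-ish tests."""
    spec = SceneSpec(shape=SowShapeParams(yaw=5.0, lateral_offset=30.0),
                     intrinsics=HALF_RES, seed=7)
    return generate_scene(spec)
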