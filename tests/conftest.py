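import numpy as np
import pytest

from tipkinetics import synthetic as syn


@pytest.fixture(scope="session")
def default_geom():
    return syn.TubeGeometry()


@pytest.fixture(scope="session")
def noiseless_stack():
    """Default pulsed-growth movie without noise, with its ground truth."""
    kp = syn.KinematicsParams()
    geom = syn.TubeGeometry()
    truth = syn.generate_kinematics(kp, base_length_um=geom.base_length)
    stack = syn.render_stack(truth, geom, seed=0)
    return stack, truth, geom


@pytest.fixture(scope="session")
def short_noiseless_stack():
    """Shorter movie (91 frames) for pipeline-level invariance tests."""
    kp = syn.KinematicsParams(T=30.0, duration=90.0)
    geom = syn.TubeGeometry(image_shape=(72, 320))
    truth = syn.generate_kinematics(kp, base_length_um=geom.base_length)
    stack = syn.render_stack(truth, geom, seed=5)
    return stack, truth, geom


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
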