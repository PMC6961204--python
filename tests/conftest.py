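import numpy as np
import pytest

import tprspring as tp


@pytest.fixture(scope="session")
def solenoid_spec():
    return tp.SolenoidSpec(n_repeats=10, superhelical_rise=8.0,
                           superhelical_twist=15.0, intra_repeat_distance=10.0)


@pytest.fixture(scope="session")
def solenoid(solenoid_spec):
    return tp.build_solenoid(solenoid_spec)


@pytest.fixture(scope="session")
def solenoid_ann(solenoid_spec):
    return tp.solenoid_annotation(solenoid_spec)


@pytest.fixture(scope="session")
def ogt_annotation():
    return tp.load_annotation(
        __import__("tprspring.io", fromlist=["io"]).default_annotation_path())


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


def rigid_motion(coords, rng):
    """A random rotation + translation applied to (…, 3) coordinates."""
    from scipy.spatial.transform import Rotation
    rot = Rotation.random(rng=rng)
    shift = rng.uniform(-50, 50, size=3)
    return rot.apply(coords.reshape(-1, 3)).reshape(coords.shape) + shift
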