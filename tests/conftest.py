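import numpy as np
import pytest

from armalign import ScanSimConfig, build_arm_model, simulate_scan


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def arm_model():
    return build_arm_model()


@pytest.fixture(scope="session")
def clean_triplet(arm_model):
    """One noiseless scanner pose: no noise, no outliers, no dropouts."""
    cfg = ScanSimConfig(
        noise_sigma=0.0, outlier_fraction=0.0, keypoint_dropout_prob=0.0, seed=7
    )
    return simulate_scan(arm_model, 0, cfg)


@pytest.fixture(scope="session")
def noisy_triplet(arm_model):
    """One realistic pose: default noise, outliers and dropouts."""
    cfg = ScanSimConfig(seed=3)
    return simulate_scan(arm_model, 1, cfg)


def random_rigid_transform(rng, max_angle_rad=np.pi, max_shift=50.0):
    from scipy.spatial.transform import Rotation

    from armalign import RigidTransform

    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = rng.uniform(0, max_angle_rad)
    rot = Rotation.from_rotvec(angle * axis).as_matrix()
    return RigidTransform(rot, rng.uniform(-max_shift, max_shift, 3))
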