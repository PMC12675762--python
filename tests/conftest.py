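import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from spinecurve import PhantomSpec, generate_phantom  # noqa: E402


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def straight_phantom():
    """Default 6-vertebra straight phantom (4 intermediates, 30 mm spacing)."""
    return generate_phantom(PhantomSpec())


@pytest.fixture
def arc_phantom():
    """30-degree single-arc sagittal phantom, tangent-aligned endplates."""
    return generate_phantom(PhantomSpec(profile="arc", arc_angle_deg=30.0))


@pytest.fixture
def identity_poses(straight_phantom):
    seg, _ = straight_phantom
    return {seg.labels[i]: np.eye(4) for i in seg.tracked_indices}


def random_rigid(rng):
    """Uniformly random rigid transform (for oracle tests)."""
    from scipy.spatial.transform import Rotation

    T = np.eye(4)
    T[:3, :3] = Rotation.random(random_state=int(rng.integers(2**31))).as_matrix()
    T[:3, 3] = rng.normal(scale=50.0, size=3)
    return T
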