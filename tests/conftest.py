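import numpy as np
import pytest

from echogate.calibration import WirePhantom
from echogate.simulate import default_calibration_truth, simulate_calibration_session
from echogate.tracking import USFrame


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_rigid(rng, max_angle=np.pi, max_trans=50.0):
    from echogate.transforms import RigidTransform3D
    rv = rng.uniform(-1, 1, 3)
    rv *= rng.uniform(0, max_angle) / max(np.linalg.norm(rv), 1e-12)
    return RigidTransform3D.from_rotvec(rv, rng.uniform(-max_trans, max_trans, 3))


@pytest.fixture
def phantom():
    return WirePhantom.default_cross_wire()


@pytest.fixture(scope="session")
def noiseless_session():
    """One noiseless 64-frame freehand calibration session."""
    ph = WirePhantom.default_cross_wire()
    obs, truth = simulate_calibration_session(ph, seed=3)
    return ph, obs, truth


def disk_frame(cx, cy, radius=20.0, shape=(160, 96), t_ms=0.0,
               noise_sd=0.02, rng=None):
    """Bright disk on a dark background, the tracker's canonical target."""
    rng = rng or np.random.default_rng(0)
    v, u = np.mgrid[0:shape[0], 0:shape[1]]
    img = 0.1 + 0.9 * (np.hypot(u - cx, v - cy) <= radius)
    if noise_sd > 0:
        img = img + rng.normal(0, noise_sd, shape)
    return USFrame(np.clip(img, 0, None), t_ms)
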