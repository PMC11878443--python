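import numpy as np
import pytest

from birtrack import BirTrajectory, CrystalModel, DetectorGeometry


@pytest.fixture
def det_small():
    """Small detector for fast rendering tests."""
    return DetectorGeometry(shape=(256, 256), pixel_size=0.055, distance=450.0, beamstop_radius=8.0)


@pytest.fixture
def det_wide():
    """Wider geometry: spots well separated, no diamond-mask overlap."""
    return DetectorGeometry(shape=(512, 512), pixel_size=0.055, distance=900.0, beamstop_radius=10.0)


@pytest.fixture
def ortho_model():
    return CrystalModel(cell=(10.0, 12.0, 14.0, 90.0, 90.0, 90.0), point_group="222", seed=0)


@pytest.fixture
def drift_traj():
    """150 frames at 0.01 e-/A^2 per frame, 1 deg per e-/A^2 about +y."""
    return BirTrajectory(
        n_frames=150,
        fluence_per_frame=0.01,
        drift_rate=1.0,
        drift_axis=(0.0, 1.0, 0.0),
        jitter_sd=0.0,
    )


def quaternion_oracle(R):
    """Independent axis-angle extraction via Shepperd's quaternion method.

    Kept free of scipy.spatial.transform so it can cross-check the
    implementation path.
    """
    R = np.asarray(R, dtype=float)
    t = np.trace(R)
    choices = [t, R[0, 0], R[1, 1], R[2, 2]]
    i = int(np.argmax(choices))
    if i == 0:
        r = np.sqrt(1.0 + t)
        s = 0.5 / r
        q = np.array([0.5 * r, (R[2, 1] - R[1, 2]) * s, (R[0, 2] - R[2, 0]) * s, (R[1, 0] - R[0, 1]) * s])
    else:
        j, k = (i % 3), (i % 3 + 1) % 3  # i in {1,2,3} -> axis index i-1
        a = i - 1
        b, c = (a + 1) % 3, (a + 2) % 3
        r = np.sqrt(1.0 + R[a, a] - R[b, b] - R[c, c])
        s = 0.5 / r
        q = np.empty(4)
        q[0] = (R[c, b] - R[b, c]) * s
        q[1 + a] = 0.5 * r
        q[1 + b] = (R[b, a] + R[a, b]) * s
        q[1 + c] = (R[c, a] + R[a, c]) * s
    if q[0] < 0:
        q = -q
    angle = 2.0 * np.arctan2(np.linalg.norm(q[1:]), q[0])
    n = np.linalg.norm(q[1:])
    axis = q[1:] / n if n > 1e-15 else np.array([0.0, 0.0, 1.0])
    return axis, np.rad2deg(angle)
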