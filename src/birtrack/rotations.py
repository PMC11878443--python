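"""Small rotation utilities shared by the simulator and the orientation pipeline.

Conventions: rotation matrices act on column vectors in a right-handed lab
frame; angles are in degrees unless a name says otherwise; the axis returned
by :func:`matrix_to_axis_angle` has its first nonzero component positive so
that (axis, angle) pairs are canonical and comparable.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation


def axis_angle_matrix(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Proper rotation by ``angle_deg`` about ``axis`` (need not be unit)."""
    axis = np.asarray(axis, dtype=float)
    n = np.linalg.norm(axis)
    if n == 0:
        raise ValueError("rotation axis must be nonzero")
    return Rotation.from_rotvec(axis / n * np.deg2rad(angle_deg)).as_matrix()


def canonical_axis(axis: np.ndarray) -> np.ndarray:
    """Flip sign so the first component exceeding 1e-12 in magnitude is positive."""
    axis = np.asarray(axis, dtype=float)
    for c in axis:
        if abs(c) > 1e-12:
            return axis if c > 0 else -axis
    return axis


def matrix_to_axis_angle(R: np.ndarray) -> tuple[np.ndarray, float]:
    """Axis (canonical sign) and angle in [0, 180] degrees of a rotation matrix.

    The identity returns axis (0, 0, 1) by convention.
    """
    rotvec = Rotation.from_matrix(np.asarray(R, dtype=float)).as_rotvec()
    angle = np.linalg.norm(rotvec)
    if angle < 1e-15:
        return np.array([0.0, 0.0, 1.0]), 0.0
    axis = rotvec / angle
    cax = canonical_axis(axis)
    return cax, float(np.rad2deg(angle))


def procrustes_rotation(M0: np.ndarray, Mi: np.ndarray) -> np.ndarray:
    """Proper rotation R minimizing ||R @ M0 - Mi||_F (Kabsch solution).

    With exact rigid-motion inputs this equals ``Mi @ inv(M0)``; with small
    non-orthogonal noise in the matrices it projects onto SO(3).
    """
    M0 = np.asarray(M0, dtype=float)
    Mi = np.asarray(Mi, dtype=float)
    H = Mi @ M0.T
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, 1.0, d])
    R = U @ D @ Vt
    if np.linalg.matrix_rank(H, tol=1e-10) < 3 and not np.allclose(M0, Mi):
        raise np.linalg.LinAlgError("rank-deficient input to Procrustes fit")
    return R


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (Haar measure) from ``rng``."""
    q = rng.normal(size=4)
    return Rotation.from_quat(q / np.linalg.norm(q)).as_matrix()
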