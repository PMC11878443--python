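"""Kinematic still-diffraction geometry shared by the simulator and refiner.

The orientation matrix ``M`` has the real-space cell vectors a, b, c (Å) as
its columns in the lab frame, beam along +z. The reciprocal basis is
``B = inv(M).T`` (columns a*, b*, c*, Å⁻¹, no 2π). A reflection h is excited
when its angular excitation error — the distance of ``q = B @ h`` from the
Ewald sphere, scaled by the d-spacing into an angle — is below the mosaic
rocking half-width.
"""

from __future__ import annotations

import numpy as np

from .geometry import DetectorGeometry


def reciprocal_basis(M: np.ndarray) -> np.ndarray:
    """Columns a*, b*, c* of the reciprocal lattice for cell-vector matrix M."""
    return np.linalg.inv(np.asarray(M, dtype=float)).T


def enumerate_hkl(M: np.ndarray, resolution_limit: float) -> np.ndarray:
    """All integer (h, k, l) ≠ (0,0,0) with d-spacing ≥ ``resolution_limit``."""
    lengths = np.linalg.norm(M, axis=0)
    hmax = np.ceil(lengths / resolution_limit).astype(int)
    grids = np.meshgrid(*(np.arange(-m, m + 1) for m in hmax), indexing="ij")
    hkl = np.stack([g.ravel() for g in grids], axis=1)
    hkl = hkl[np.any(hkl != 0, axis=1)]
    q = hkl @ reciprocal_basis(M).T
    d = 1.0 / np.linalg.norm(q, axis=1)
    return hkl[d >= resolution_limit]


def excitation_error_deg(q: np.ndarray, wavelength: float) -> np.ndarray:
    """Angular excitation error (degrees) of reciprocal points (N, 3).

    Signed distance of q from the Ewald sphere |q + k0| = 1/λ (k0 along +z),
    converted to an angle by multiplying with the d-spacing.
    """
    q = np.atleast_2d(q)
    k0 = np.array([0.0, 0.0, 1.0 / wavelength])
    dist = np.linalg.norm(q + k0, axis=1) - 1.0 / wavelength
    d = 1.0 / np.linalg.norm(q, axis=1)
    return np.rad2deg(dist * d)


def predict_reflections(
    M: np.ndarray,
    det: DetectorGeometry,
    resolution_limit: float,
    rocking_halfwidth: float,
) -> dict[str, np.ndarray]:
    """Excited reflections under orientation ``M`` and where they land.

    Returns arrays: ``hkl`` (N, 3), ``position`` (N, 2) detector (row, col),
    ``d`` (Å), ``rocking`` — triangular rocking-curve factor
    max(0, 1 − |δ|/halfwidth) — for every reflection with positive factor
    that projects onto the detector. Reflections projecting outside the
    detector are silently dropped.
    """
    hkl = enumerate_hkl(M, resolution_limit)
    q = hkl @ reciprocal_basis(M).T
    delta = excitation_error_deg(q, det.wavelength)
    rock = np.clip(1.0 - np.abs(delta) / rocking_halfwidth, 0.0, None)
    sel = rock > 0
    hkl, q, rock = hkl[sel], q[sel], rock[sel]
    k_out = q + np.array([0.0, 0.0, 1.0 / det.wavelength])
    pos = det.project(k_out)
    inside = (
        (pos[:, 0] >= 0)
        & (pos[:, 0] <= det.shape[0] - 1)
        & (pos[:, 1] >= 0)
        & (pos[:, 1] <= det.shape[1] - 1)
        & (k_out[:, 2] > 0)
    )
    d = 1.0 / np.linalg.norm(q, axis=1)
    return {
        "hkl": hkl[inside],
        "position": pos[inside],
        "d": d[inside],
        "rocking": rock[inside],
        "q": q[inside],
    }
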