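"""Orientation-track cleaning and net beam-induced reorientation (BIR).

Serial still-frame indexing of a dose series yields one lattice-orientation
matrix per frame, but two artifacts obscure the physics: the indexing
program may return any symmetry-equivalent setting of the lattice
(point-group ambiguity), and individual frames may be mis-indexed outright.
This module resolves the ambiguity by walking the series and snapping each
frame to the symmetry-equivalent orientation nearest its predecessor,
rejects outlier frames by a two-standard-deviation rule on the matrix
components, and then decomposes the cleaned track into rotation axes and
angles relative to the first frame — the net reorientation of the crystal
under the beam.

Matrices follow the package convention: columns are the real-space cell
vectors a, b, c in Å, lab frame, beam along +z.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd

from .geometry import DetectorGeometry
from .rotations import matrix_to_axis_angle, procrustes_rotation

logger = logging.getLogger(__name__)

__all__ = [
    "OrientationSeries",
    "RotationSummary",
    "RefinementResult",
    "point_group_rotations",
    "disambiguate",
    "reject_misindexed",
    "relative_rotation",
    "net_rotation",
    "detect_quake",
    "refine_orientation",
    "read_orientation_table",
    "write_orientation_table",
]


def cell_of_matrix(M: np.ndarray) -> np.ndarray:
    """(a, b, c, α, β, γ) implied by a cell-vector matrix (Å, degrees)."""
    M = np.asarray(M, dtype=float)
    a, b, c = (np.linalg.norm(M[:, j]) for j in range(3))

    def ang(u, v):
        return np.rad2deg(np.arccos(np.clip(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)), -1, 1)))

    return np.array([a, b, c, ang(M[:, 1], M[:, 2]), ang(M[:, 0], M[:, 2]), ang(M[:, 0], M[:, 1])])


@dataclass
class OrientationSeries:
    """Per-frame lattice orientations of one crystal through a dose series."""

    matrices: np.ndarray  # (n_frames, 3, 3), columns = cell vectors
    fluence_axis: np.ndarray  # e- / Å^2, end of each frame
    valid: np.ndarray | None = None
    cell: tuple[float, float, float, float, float, float] | None = None
    point_group: str = "1"
    truth: dict | None = None  # generator ground truth; absent for real data

    def __post_init__(self) -> None:
        self.matrices = np.asarray(self.matrices, dtype=float)
        self.fluence_axis = np.asarray(self.fluence_axis, dtype=float)
        if self.matrices.ndim != 3 or self.matrices.shape[1:] != (3, 3):
            raise ValueError("matrices must have shape (n_frames, 3, 3)")
        if len(self.fluence_axis) != len(self.matrices):
            raise ValueError("fluence_axis length must match frame count")
        if self.valid is None:
            self.valid = np.ones(len(self.matrices), dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)

    @property
    def n_frames(self) -> int:
        return len(self.matrices)

    def check_cell(self, length_tol: float = 0.01, angle_tol: float = 1.0) -> np.ndarray:
        """Per-frame flag: does the matrix reproduce the enforced cell?

        ``length_tol`` is relative on a, b, c; ``angle_tol`` absolute degrees.
        """
        if self.cell is None:
            return np.ones(self.n_frames, dtype=bool)
        ref = np.asarray(self.cell, dtype=float)
        ok = np.ones(self.n_frames, dtype=bool)
        for i, M in enumerate(self.matrices):
            c = cell_of_matrix(M)
            ok[i] = np.all(np.abs(c[:3] - ref[:3]) <= length_tol * ref[:3]) and np.all(
                np.abs(c[3:] - ref[3:]) <= angle_tol
            )
        return ok


@dataclass
class RotationSummary:
    """Axis–angle decomposition of a cleaned orientation track vs frame 0."""

    frame_index: np.ndarray  # indices of the valid frames used
    fluence: np.ndarray
    per_frame_angle: np.ndarray  # degrees, frame i vs frame 0
    step_angle: np.ndarray  # degrees, frame i vs previous valid frame
    per_vector_angles: np.ndarray  # (n, 3): drift of cell vectors a, b, c
    final_axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    final_angle: float = 0.0
    final_fluence: float = 0.0


# ---------------------------------------------------------------------------
# symmetry

# Rotational point groups -> a representative (primitive, symmorphic) space
# group whose proper rotation parts ARE the point group in the crystal basis.
_PG_TO_SG = {
    "1": "P1", "-1": "P1",
    "2": "P2", "m": "P1", "2/m": "P2",
    "222": "P222", "mm2": "P2", "mmm": "P222",
    "4": "P4", "-4": "P2", "4/m": "P4",
    "422": "P422", "4mm": "P4", "-42m": "P222", "4/mmm": "P422",
    "3": "P3", "-3": "P3",
    "32": "P321", "3m": "P3", "-3m": "P321",
    "6": "P6", "-6": "P3", "6/m": "P6",
    "622": "P622", "6mm": "P6", "-6m2": "P312", "6/mmm": "P622",
    "23": "P23", "m-3": "P23",
    "432": "P432", "-43m": "P23", "m-3m": "P432",
}


def point_group_rotations(symbol: str) -> list[np.ndarray]:
    """Proper rotation operations of a point group, in the crystal basis.

    ``symbol`` may be a rotational point-group symbol ("1", "222", "422", …)
    or a full space-group symbol ("P212121"); for space groups the rotation
    parts of all operations are taken and improper ones discarded. Returned
    as integer 3×3 matrices acting on (h, k, l) columns; the identity is
    always present. Post-multiplying an orientation matrix by any of these
    preserves the cell metric exactly.
    """
    symbol = symbol.strip()
    sg = gemmi.find_spacegroup_by_name(_PG_TO_SG.get(symbol, symbol))
    if sg is None:
        raise ValueError(f"unknown point-group or space-group symbol: {symbol!r}")
    seen: dict[tuple, np.ndarray] = {}
    for op in sg.operations():
        R = np.array(op.rot, dtype=float) / gemmi.Op.DEN
        Ri = np.rint(R).astype(int)
        if not np.allclose(R, Ri) or np.linalg.det(Ri) <= 0:
            continue
        seen.setdefault(tuple(Ri.ravel()), Ri)
    ops = list(seen.values())
    # identity first, then a deterministic order
    ops.sort(key=lambda S: (not np.array_equal(S, np.eye(3, dtype=int)), tuple(S.ravel())))
    return ops


def disambiguate(series: OrientationSeries, ops: list[np.ndarray] | None = None) -> OrientationSeries:
    """Resolve point-group indexing ambiguity by nearest-neighbor chaining.

    The first frame is taken as ground truth; each subsequent frame is
    replaced by the symmetry-equivalent setting ``M @ S`` nearest (Frobenius
    norm on the 9 components) the previous, already corrected, frame. Ties
    go to the lowest op index, so the result is deterministic.

    Frames already flagged invalid are still snapped to their nearest
    setting but do not serve as the chaining anchor, so on a series that
    has been through :func:`reject_misindexed` the chain runs across the
    gaps instead of being derailed by an outlier frame. On a fresh series
    (all frames valid) this is the plain frame-to-frame walk.
    """
    if ops is None:
        ops = point_group_rotations(series.point_group)
    out = series.matrices.copy()
    prev = out[0]
    for i in range(1, series.n_frames):
        cands = np.stack([out[i] @ S for S in ops])
        dist = np.linalg.norm(cands - prev, axis=(1, 2))
        out[i] = cands[int(np.argmin(dist))]
        if series.valid[i]:
            prev = out[i]
    return replace(series, matrices=out, valid=series.valid.copy())


def reject_misindexed(series: OrientationSeries, sigma_k: float = 2.0) -> OrientationSeries:
    """Flag frames whose matrix jumps away from BOTH neighbors.

    For each of the nine matrix components the standard deviation σ over all
    frames of the series is computed once. Frame i is discarded when, for
    some component, its difference from the same component in the previous
    AND the next frame both exceed ``sigma_k`` σ. Endpoint frames use their
    single neighbor for both comparisons.
    """
    n = series.n_frames
    if np.count_nonzero(series.valid) < 3:
        logger.warning("reject_misindexed: fewer than 3 valid frames, no-op")
        return replace(series, matrices=series.matrices.copy(), valid=series.valid.copy())
    X = series.matrices.reshape(n, 9)
    sigma = X.std(axis=0)
    # a component that never varies (e.g. fixed by the drift axis) carries no
    # information; floor its sigma at the numerical noise of the data scale
    sigma = np.maximum(sigma, 1e-9 * max(np.abs(X).max(), 1.0))
    valid = series.valid.copy()
    for i in range(n):
        lo = X[i - 1] if i > 0 else X[i + 1]
        hi = X[i + 1] if i < n - 1 else X[i - 1]
        bad = (np.abs(X[i] - lo) > sigma_k * sigma) & (np.abs(X[i] - hi) > sigma_k * sigma)
        if np.any(bad):
            valid[i] = False
    n_rej = int(np.count_nonzero(series.valid & ~valid))
    if n_rej:
        logger.info("reject_misindexed: discarded %d frame(s)", n_rej)
    return replace(series, matrices=series.matrices.copy(), valid=valid)


def clean_series(series: OrientationSeries, sigma_k: float = 2.0, ops: list[np.ndarray] | None = None) -> OrientationSeries:
    """Full track cleaning: disambiguate, reject outliers, re-chain.

    The second disambiguation pass anchors only on surviving frames, so a
    mis-indexed frame in the middle of the series cannot flip the rest of
    the track onto another symmetry branch.
    """
    if ops is None:
        ops = point_group_rotations(series.point_group)
    out = disambiguate(series, ops)
    out = reject_misindexed(out, sigma_k=sigma_k)
    return disambiguate(out, ops)


def relative_rotation(M0: np.ndarray, Mi: np.ndarray) -> tuple[np.ndarray, float]:
    """Axis (canonical sign) and angle (deg) of the rotation taking M0 to Mi.

    The rotation is the proper orthogonal Procrustes fit of Mi's columns to
    M0's, which coincides with ``Mi @ inv(M0)`` for exact rigid motion and
    projects onto SO(3) for slightly noisy indexed matrices. The identity
    returns axis (0, 0, 1) and angle 0 by convention.
    """
    R = procrustes_rotation(M0, Mi)
    return matrix_to_axis_angle(R)


def _vector_angles(M0: np.ndarray, Mi: np.ndarray) -> np.ndarray:
    cos = np.sum(M0 * Mi, axis=0) / (np.linalg.norm(M0, axis=0) * np.linalg.norm(Mi, axis=0))
    return np.rad2deg(np.arccos(np.clip(cos, -1.0, 1.0)))


def net_rotation(series: OrientationSeries, max_fluence: float | None = None) -> RotationSummary:
    """Net reorientation of the lattice relative to the first valid frame.

    Per valid frame: the rotation angle vs frame 0, the step rotation vs the
    previous valid frame, and the angular drift of each cell vector a, b, c
    from its initial direction. The final axis/angle are taken at the last
    valid frame at or before ``max_fluence`` (series end when omitted).
    """
    idx = np.flatnonzero(series.valid)
    if len(idx) < 2:
        raise ValueError("need at least two valid frames for net rotation")
    M0 = series.matrices[idx[0]]
    angles = np.empty(len(idx))
    steps = np.empty(len(idx))
    vec = np.empty((len(idx), 3))
    axes = np.empty((len(idx), 3))
    prev = M0
    for j, i in enumerate(idx):
        Mi = series.matrices[i]
        axes[j], angles[j] = relative_rotation(M0, Mi)
        _, steps[j] = relative_rotation(prev, Mi)
        vec[j] = _vector_angles(M0, Mi)
        prev = Mi
    flu = series.fluence_axis[idx]
    j_final = len(idx) - 1
    if max_fluence is not None:
        within = np.flatnonzero(flu <= max_fluence)
        if len(within) == 0:
            raise ValueError("no valid frame at or before the requested fluence")
        j_final = within[-1]
    return RotationSummary(
        frame_index=idx,
        fluence=flu,
        per_frame_angle=angles,
        step_angle=steps,
        per_vector_angles=vec,
        final_axis=axes[j_final],
        final_angle=float(angles[j_final]),
        final_fluence=float(flu[j_final]),
    )


def detect_quake(summary: RotationSummary, threshold: float = 1.0) -> float | None:
    """Fluence of a crystal quake — an abrupt consensus reorientation.

    Returns the accumulated fluence AFTER WHICH the largest frame-to-frame
    rotation occurred, if that step exceeds ``threshold`` degrees; otherwise
    ``None``. A quake between frames i−1 and i is reported at the fluence of
    frame i−1 (the dose delivered when the jump happened).
    """
    if len(summary.step_angle) < 3:
        return None
    i = int(np.argmax(summary.step_angle[1:])) + 1  # step_angle[0] is frame 0 vs itself
    if summary.step_angle[i] <= threshold:
        return None
    return float(summary.fluence[i - 1])


@dataclass
class RefinementResult:
    matrix: np.ndarray
    success: bool
    n_assigned: int
    iterations: int
    rms_residual_px: float = float("nan")


def refine_orientation(
    spots,
    candidate: np.ndarray,
    cell: tuple | None,
    det: DetectorGeometry,
    rocking_halfwidth: float = 0.3,
    resolution_limit: float = 1.0,
    capture_radius: float = 6.0,
    max_iter: int = 10,
    tol_deg: float = 1e-4,
) -> RefinementResult:
    """Refine an approximate orientation against observed spot positions.

    Predicts near-Ewald-sphere reflections under the candidate, assigns each
    observed spot to its nearest prediction within ``capture_radius`` pixels,
    solves for the proper rotation minimizing squared residuals between the
    matched scattering vectors (Kabsch), and iterates. Refinement is refused
    (``success=False``, candidate returned) when fewer than 3 spots can be
    assigned — e.g. a candidate so far off that the excited set is disjoint.
    """
    from .diffraction import predict_reflections  # local import avoids cycle

    M = np.asarray(candidate, dtype=float).copy()
    centers = np.asarray(spots.centers, dtype=float)
    k0 = np.array([0.0, 0.0, 1.0 / det.wavelength])
    iterations = 0
    rms = float("nan")
    for iterations in range(1, max_iter + 1):
        pred = predict_reflections(M, det, resolution_limit, rocking_halfwidth)
        if len(pred["position"]) == 0:
            return RefinementResult(np.asarray(candidate, float), False, 0, iterations)
        # nearest prediction for each observed spot
        diff = centers[:, None, :] - pred["position"][None, :, :]
        dist = np.linalg.norm(diff, axis=2)
        nearest = np.argmin(dist, axis=1)
        ok = dist[np.arange(len(centers)), nearest] <= capture_radius
        if np.count_nonzero(ok) < 3:
            return RefinementResult(np.asarray(candidate, float), False, int(np.count_nonzero(ok)), iterations)
        # a detector position fixes only the DIRECTION of the scattered ray;
        # the predicted reflection may sit anywhere inside the rocking width,
        # so fit the rotation on unit rays, not on back-projected q vectors
        # (which would drag every reflection onto the Ewald sphere).
        u_pred = pred["q"][nearest[ok]] + k0
        u_pred /= np.linalg.norm(u_pred, axis=1)[:, None]
        rows, cols = centers[ok, 0], centers[ok, 1]
        r0, c0 = det.beam_center
        x = (cols - c0) * det.pixel_size
        y = (rows - r0) * det.pixel_size
        u_obs = np.column_stack([x, y, np.full_like(x, det.distance)])
        u_obs /= np.linalg.norm(u_obs, axis=1)[:, None]
        # proper rotation u_pred -> u_obs
        H = u_obs.T @ u_pred
        U, _, Vt = np.linalg.svd(H)
        D = np.diag([1.0, 1.0, np.sign(np.linalg.det(U @ Vt))])
        R = U @ D @ Vt
        _, dtheta = matrix_to_axis_angle(R)
        M = R @ M
        res = pred["position"][nearest[ok]] - centers[ok]
        rms = float(np.sqrt(np.mean(np.sum(res**2, axis=1))))
        if dtheta < tol_deg:
            break
    return RefinementResult(M, True, int(np.count_nonzero(ok)), iterations, rms)


# ---------------------------------------------------------------------------
# tabular I/O: frame, 9 matrix components (row-major), fluence

_COMPONENTS = ["a_x", "b_x", "c_x", "a_y", "b_y", "c_y", "a_z", "b_z", "c_z"]


def write_orientation_table(series: OrientationSeries, path: str | Path) -> None:
    df = pd.DataFrame(series.matrices.reshape(series.n_frames, 9), columns=_COMPONENTS)
    df.insert(0, "frame", np.arange(series.n_frames))
    df["fluence"] = series.fluence_axis
    df["valid"] = series.valid.astype(int)
    df.to_csv(path, sep="\t", index=False, float_format="%.9g")


def read_orientation_table(path: str | Path, point_group: str = "1", cell: tuple | None = None) -> OrientationSeries:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _COMPONENTS + ["fluence"] if c not in df.columns]
    if missing:
        raise ValueError(f"orientation table missing columns: {missing}")
    matrices = df[_COMPONENTS].to_numpy(float).reshape(-1, 3, 3)
    valid = df["valid"].to_numpy(bool) if "valid" in df.columns else None
    return OrientationSeries(
        matrices=matrices,
        fluence_axis=df["fluence"].to_numpy(float),
        valid=valid,
        cell=cell,
        point_group=point_group,
    )
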