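"""Ground-truth dose-series simulator for beam-induced reorientation studies.

A stationary nanocrystal under continuous electron illumination is modelled
as a rigid lattice whose consensus orientation changes with accumulated
fluence: a smooth drift (constant angular rate about a fixed lab axis),
optional per-frame angular jitter, and an optional abrupt reorientation — a
crystal quake — at a critical fluence. On top of the orientation track the
simulator renders still-diffraction frames with resolution-dependent
intensity decay, emulates the symmetry ambiguity and occasional mis-indexing
of serial still indexing, and produces imaging-mode stacks with migrating
bend-contour bands. Every generator records its ground truth so each
analysis stage can be tested by parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import gemmi
import numpy as np

from .diffraction import predict_reflections
from .frame_io import FrameStack
from .geometry import DetectorGeometry
from .orientation import OrientationSeries, point_group_rotations
from .rotations import axis_angle_matrix, matrix_to_axis_angle, random_rotation

__all__ = [
    "CrystalModel",
    "BirTrajectory",
    "simulate_orientation_track",
    "scramble_indexing",
    "render_diffraction_frame",
    "render_dose_series",
    "generate_bend_contour_stack",
]


@dataclass
class CrystalModel:
    """Static crystal properties for the simulator.

    ``decay_rate`` α parameterizes the resolution-dependent decay law
    I(d, D) = I0 · exp(−α D / d²) with D the fluence in e⁻ Å⁻² and d the
    d-spacing in Å, so fine spatial frequencies fade first.
    ``base_intensities`` is either a mapping (h,k,l) → I0, or a scalar mean
    around which per-reflection values are drawn deterministically
    (log-normal, seeded per reflection index).
    """

    cell: tuple[float, float, float, float, float, float] = (10.0, 12.0, 14.0, 90.0, 90.0, 90.0)
    point_group: str = "1"
    resolution_limit: float = 1.0
    base_intensities: dict | float = 2000.0
    decay_rate: float = 1.0
    rocking_halfwidth: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if any(x <= 0 for x in self.cell):
            raise ValueError("cell constants must be positive")
        if not 0 < self.rocking_halfwidth < 5:
            raise ValueError("rocking_halfwidth must be in (0, 5) degrees")
        if self.decay_rate < 0:
            raise ValueError("decay_rate must be non-negative")

    def cell_matrix(self) -> np.ndarray:
        """Cell vectors a, b, c as columns, standard PDB orthogonalization."""
        m = gemmi.UnitCell(*self.cell).orth.mat
        return np.array(m.tolist(), dtype=float)

    def base_intensity(self, hkl: np.ndarray) -> np.ndarray:
        """Per-reflection I0; deterministic in (seed, h, k, l)."""
        hkl = np.atleast_2d(hkl)
        if isinstance(self.base_intensities, dict):
            return np.array([self.base_intensities.get(tuple(int(x) for x in h), 0.0) for h in hkl])
        out = np.empty(len(hkl))
        for j, h in enumerate(hkl):
            rng = np.random.default_rng([self.seed, *(int(x) + 4096 for x in h)])
            out[j] = self.base_intensities * rng.lognormal(mean=0.0, sigma=0.4)
        return out


@dataclass
class BirTrajectory:
    """Time course of the consensus reorientation over a dose series."""

    n_frames: int = 150
    fluence_per_frame: float = 0.01
    drift_rate: float = 1.0  # degrees per e-/Å^2
    drift_axis: tuple[float, float, float] = (0.0, 1.0, 0.0)
    jitter_sd: float = 0.0  # degrees per frame
    quake_fluence: float | None = None
    quake_angle: float = 0.0
    quake_axis: tuple[float, float, float] = (1.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("need at least 2 frames")
        if self.fluence_per_frame <= 0:
            raise ValueError("fluence_per_frame must be positive")
        if self.drift_rate < 0 or self.jitter_sd < 0 or self.quake_angle < 0:
            raise ValueError("rates and angles must be non-negative")
        for ax in (self.drift_axis, self.quake_axis):
            if abs(np.linalg.norm(ax) - 1.0) > 1e-9:
                raise ValueError("axes must be unit-norm within 1e-9")


def simulate_orientation_track(model: CrystalModel, traj: BirTrajectory) -> OrientationSeries:
    """Ground-truth orientation matrices of a drifting (and quaking) crystal.

    Frame 0 holds the reference orientation (the cell's orthogonalization
    matrix). Frame i is rotated by ``drift_rate × (i · fluence_per_frame)``
    about ``drift_axis``, composed with independent per-frame jitter (angle
    |N(0, jitter_sd²)| about a random axis) and, once the frame-start
    fluence reaches ``quake_fluence``, the quake rotation. The imposed final
    axis/angle and per-frame truth are recorded in ``series.truth``.
    """
    rng = np.random.default_rng(model.seed)
    M0 = model.cell_matrix()
    n = traj.n_frames
    mats = np.empty((n, 3, 3))
    Rq = axis_angle_matrix(np.asarray(traj.quake_axis), traj.quake_angle)
    for i in range(n):
        flu = i * traj.fluence_per_frame  # dose accumulated before frame i
        R = axis_angle_matrix(np.asarray(traj.drift_axis), traj.drift_rate * flu)
        if traj.quake_fluence is not None and i > 0 and flu >= traj.quake_fluence:
            R = Rq @ R
        if traj.jitter_sd > 0:
            jit_axis = rng.normal(size=3)
            jit_axis /= np.linalg.norm(jit_axis)
            jit_angle = abs(rng.normal(scale=traj.jitter_sd))
            R = axis_angle_matrix(jit_axis, jit_angle) @ R
        mats[i] = R @ M0
    axis, angle = matrix_to_axis_angle(mats[-1] @ np.linalg.inv(M0))
    fluence_axis = (np.arange(n) + 1.0) * traj.fluence_per_frame
    truth = {
        "final_angle": angle,
        "final_axis": axis,
        "drift_rate": traj.drift_rate,
        "drift_axis": np.asarray(traj.drift_axis, float),
        "quake_fluence": traj.quake_fluence,
        "quake_angle": traj.quake_angle,
        "bad_frames": np.zeros(n, dtype=bool),
    }
    return OrientationSeries(
        matrices=mats,
        fluence_axis=fluence_axis,
        cell=model.cell,
        point_group=model.point_group,
        truth=truth,
    )


def scramble_indexing(
    series: OrientationSeries,
    model: CrystalModel,
    noise_sd: float = 0.0,
    misindex_fraction: float = 0.0,
    seed: int = 0,
) -> OrientationSeries:
    """Emulate serial-indexing output: ambiguous settings, noise, outliers.

    Each frame's matrix is post-multiplied by a uniformly random proper
    point-group operation of ``model.point_group`` (an exact isometry of the
    lattice, so cell constants are preserved), then perturbed by additive
    zero-mean Gaussian component noise of SD ``noise_sd``. A
    ``misindex_fraction`` of frames (never frame 0, which downstream
    cleaning treats as ground truth) are replaced by random orientations of
    the same cell and flagged in ``truth['bad_frames']``.
    """
    if not 0 <= misindex_fraction < 0.5:
        raise ValueError("misindex_fraction must be in [0, 0.5)")
    ops = point_group_rotations(model.point_group)
    rng = np.random.default_rng(seed)
    n = series.n_frames
    mats = series.matrices.copy()
    for i in range(n):
        S = ops[rng.integers(len(ops))]
        mats[i] = mats[i] @ S
    bad = np.zeros(n, dtype=bool)
    n_bad = int(round(misindex_fraction * n))
    if n_bad:
        bad_idx = rng.choice(np.arange(1, n), size=n_bad, replace=False)
        bad[bad_idx] = True
        for i in bad_idx:
            mats[i] = random_rotation(rng) @ series.matrices[0]
    if noise_sd > 0:
        mats += rng.normal(scale=noise_sd, size=mats.shape)
    truth = dict(series.truth or {})
    truth["bad_frames"] = bad | truth.get("bad_frames", np.zeros(n, dtype=bool))
    return OrientationSeries(
        matrices=mats,
        fluence_axis=series.fluence_axis.copy(),
        cell=series.cell,
        point_group=series.point_group,
        truth=truth,
    )


def render_diffraction_frame(
    model: CrystalModel,
    orientation: np.ndarray,
    fluence: float,
    det: DetectorGeometry,
    seed: int = 0,
    background: float = 5.0,
    spot_sigma: float = 1.2,
    poisson: bool = True,
) -> np.ndarray:
    """Render one still-diffraction frame as float64 counts.

    Every reflection within the resolution limit whose angular excitation
    error is below the rocking half-width is drawn as a 2D Gaussian at its
    projected detector position, with integrated intensity
    I0 · exp(−α · fluence / d²) · (triangular rocking factor). A flat
    background is added, Poisson noise applied (unless disabled), and the
    beamstop disc zeroed. Reflections projecting off the detector are
    silently skipped.
    """
    pred = predict_reflections(orientation, det, model.resolution_limit, model.rocking_halfwidth)
    img = np.zeros(det.shape, dtype=float)
    if len(pred["hkl"]):
        inten = (
            model.base_intensity(pred["hkl"])
            * np.exp(-model.decay_rate * fluence / pred["d"] ** 2)
            * pred["rocking"]
        )
        half = int(np.ceil(4 * spot_sigma))
        for (r, c), I in zip(pred["position"], inten):
            if I <= 0:
                continue
            r_lo, r_hi = int(np.floor(r)) - half, int(np.floor(r)) + half + 1
            c_lo, c_hi = int(np.floor(c)) - half, int(np.floor(c)) + half + 1
            rr = np.arange(max(r_lo, 0), min(r_hi, det.shape[0]))
            cc = np.arange(max(c_lo, 0), min(c_hi, det.shape[1]))
            if len(rr) == 0 or len(cc) == 0:
                continue
            g = np.exp(-((rr[:, None] - r) ** 2 + (cc[None, :] - c) ** 2) / (2 * spot_sigma**2))
            img[np.ix_(rr, cc)] += I * g / (2 * np.pi * spot_sigma**2)
    img += background
    if poisson:
        img = np.random.default_rng(seed).poisson(img).astype(float)
    img[det.beamstop_mask()] = 0.0
    return img


def render_dose_series(
    model: CrystalModel,
    series: OrientationSeries,
    det: DetectorGeometry,
    exposure_per_frame: float = 1.0,
    background: float = 5.0,
    poisson: bool = True,
) -> FrameStack:
    """Render a whole dose series from an orientation track.

    Frame i is rendered at the dose accumulated before it (frame-start
    fluence), consistent with :func:`simulate_orientation_track`. The
    returned stack's flux is chosen so its end-of-frame fluence axis matches
    the orientation series'. Ground truth (spot positions and d-spacings of
    frame 0) is attached as ``stack.truth``.
    """
    fpf = float(series.fluence_axis[0])
    frames = np.empty((series.n_frames, *det.shape))
    for i in range(series.n_frames):
        frames[i] = render_diffraction_frame(
            model,
            series.matrices[i],
            fluence=i * fpf,
            det=det,
            seed=model.seed * 100003 + i,
            background=background,
            poisson=poisson,
        )
    stack = FrameStack(
        data=frames,
        exposure_per_frame=exposure_per_frame,
        flux=fpf / exposure_per_frame,
        detector=det,
        fluence_axis=series.fluence_axis.copy(),
    )
    pred0 = predict_reflections(series.matrices[0], det, model.resolution_limit, model.rocking_halfwidth)
    stack.truth = {  # type: ignore[attr-defined]
        "positions": pred0["position"],
        "d": pred0["d"],
        "hkl": pred0["hkl"],
        "rocking": pred0["rocking"],
        "intensity0": model.base_intensity(pred0["hkl"]) * pred0["rocking"],
        "decay_rate": model.decay_rate,
    }
    return stack


def generate_bend_contour_stack(
    n_frames: int = 100,
    shape: tuple[int, int] = (128, 128),
    band_params: dict | None = None,
    fluence_per_frame: float = 0.01,
    seed: int = 0,
) -> FrameStack:
    """Imaging-mode stack of a crystal crossed by migrating dark bands.

    The crystal is an elliptical bright region on a dim background; bend
    contours are Gaussian-profile dark bands perpendicular to the long axis
    whose column positions migrate at ``band_params['speed']`` pixels per
    e⁻ Å⁻² until ``band_params['settle_fluence']``, after which they are
    static. Additive Gaussian read noise on every frame. Band positions per
    frame are recorded in ``stack.truth``.
    """
    p = {"width": 4.0, "contrast": 0.6, "speed": 30.0, "settle_fluence": 0.5, "noise_sd": 1.0, "n_bands": 3}
    p.update(band_params or {})
    if p["speed"] < 0:
        raise ValueError("band speed must be non-negative")
    rng = np.random.default_rng(seed)
    rows, cols = shape
    rr, cc = np.indices(shape)
    r0, c0 = (rows - 1) / 2, (cols - 1) / 2
    crystal = ((rr - r0) / (0.38 * rows)) ** 2 + ((cc - c0) / (0.45 * cols)) ** 2 <= 1.0
    base_cols = np.linspace(0.25 * cols, 0.6 * cols, p["n_bands"])
    frames = np.empty((n_frames, rows, cols))
    band_centers = np.empty((n_frames, p["n_bands"]))
    for t in range(n_frames):
        flu = min(t * fluence_per_frame, p["settle_fluence"])
        centers = base_cols + p["speed"] * flu
        band_centers[t] = centers
        profile = np.ones(cols)
        for x0 in centers:
            profile *= 1.0 - p["contrast"] * np.exp(-((np.arange(cols) - x0) ** 2) / (2 * p["width"] ** 2))
        img = np.where(crystal, 100.0 * profile[None, :], 20.0)
        frames[t] = img + rng.normal(scale=p["noise_sd"], size=shape)
    stack = FrameStack(
        data=frames,
        exposure_per_frame=1.0,
        flux=fluence_per_frame,
        temperature_label="293 K",
    )
    stack.truth = {  # type: ignore[attr-defined]
        "band_centers": band_centers,
        "speed": p["speed"],
        "settle_fluence": p["settle_fluence"],
        "crystal_mask": crystal,
    }
    return stack
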