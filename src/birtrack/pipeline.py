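"""End-to-end orchestration: configs, report bundles and canonical fixtures.

`run_still_series` ties the still-series stages together — spot tracing,
trace clustering, derivative fluctuation metrics, orientation cleaning and
net-rotation decomposition — and writes a report bundle whose manifest
(inputs hashed, parameters, seed, version) suffices to reproduce every
number in it. `make_fixtures` writes the small canonical datasets used for
demonstration and testing: drift-only and quake orientation tracks, a
decay-only rendered diffraction series, a static imaging stack and a
migrating-band stack, each with its ground-truth manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import __version__
from .frame_io import FrameStack, read_manifest, read_stack, write_manifest, write_stack
from .geometry import DetectorGeometry
from .orientation import (
    clean_series,
    detect_quake,
    net_rotation,
    point_group_rotations,
    read_orientation_table,
    write_orientation_table,
)
from .spot_tracing import (
    derivative_profile,
    detection_image,
    find_spots,
    integrate_traces,
    summed_trace,
    write_traces,
)
from .trace_clustering import cluster_traces, normalize_per_trace

logger = logging.getLogger(__name__)


class ValidityError(RuntimeError):
    """A stage failed to converge or its input failed a validity check."""


@dataclass
class RunConfig:
    """All knobs of a still-series run; defaults follow standard practice.

    threshold_factor 1.25× background, 25-px diamond masks, brightest 20%
    of traces, 0.1 e⁻ Å⁻² derivative bins, five k-means clusters and a 2σ
    mis-index rule.
    """

    stack_path: str = ""
    orientation_path: str = ""
    out_dir: str = "report"
    threshold_factor: float = 1.25
    mask_radius: int = 25
    top_fraction: float = 0.2
    bin_width: float = 0.1
    k: int = 5
    sigma_k: float = 2.0
    quake_threshold: float = 1.0
    point_group: str = "1"
    seed: int = 0
    plots: bool = False

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        raw = read_manifest(path)
        cfg = cls()
        for key, value in raw.items():
            if not hasattr(cfg, key):
                raise ValueError(f"unknown config key {key!r}")
            current = getattr(cfg, key)
            if isinstance(current, bool):
                value = str(value).lower() in ("1", "true", "yes")
            elif isinstance(current, int):
                value = int(value)
            elif isinstance(current, float):
                value = float(value)
            else:
                value = str(value)
            setattr(cfg, key, value)
        return cfg

    def to_file(self, path: str | Path) -> None:
        write_manifest(path, asdict(self))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_still_series(config: RunConfig) -> dict:
    """Run the full still-series analysis and write a report bundle.

    Returns the report summary dict (also written as ``summary.json``).
    Stage failures propagate with the stage name prefixed.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"version": __version__, "seed": config.seed, "inputs": {}}

    if config.stack_path:
        stack_path = Path(config.stack_path)
        if not stack_path.exists():
            raise FileNotFoundError(f"stack not found: {stack_path}")
        stack = read_stack(stack_path)
        if stack_path.is_file():
            summary["inputs"][str(stack_path)] = _sha256(stack_path)
        try:
            det_img = detection_image(stack)
            spots = find_spots(
                det_img,
                threshold_factor=config.threshold_factor,
                mask_radius=config.mask_radius,
                detector=stack.detector,
            )
            if len(spots) == 0:
                raise ValidityError("no spots found in detection image")
            traces = integrate_traces(stack, spots)
            write_traces(traces, out / "traces.tsv")
            total = summed_trace(traces, top_fraction=config.top_fraction)
            prof = derivative_profile(total, stack.fluence_axis, bin_width=config.bin_width)
            np.savetxt(
                out / "summed_trace.tsv",
                np.column_stack([stack.fluence_axis, total]),
                delimiter="\t",
                header="fluence\tnormalized_intensity",
                comments="",
            )
            np.savetxt(
                out / "derivative_profile.tsv",
                np.column_stack([prof.midpoints, prof.derivative]),
                delimiter="\t",
                header="fluence\tderivative",
                comments="",
            )
            np.savetxt(
                out / "derivative_bins.tsv",
                np.column_stack([prof.bin_edges[:-1], prof.bin_edges[1:], prof.bin_sd]),
                delimiter="\t",
                header="bin_lo\tbin_hi\tderivative_sd",
                comments="",
            )
            normed = normalize_per_trace(traces)
            if normed.n_traces >= config.k:
                result = cluster_traces(normed, k=config.k, seed=config.seed)
                np.savetxt(
                    out / "clusters.tsv",
                    np.column_stack([normed.ids, result.labels]),
                    fmt="%d",
                    delimiter="\t",
                    header="spot\tcluster",
                    comments="",
                )
                summary["clustering"] = {"k": result.k, "inertia": result.inertia}
            summary["spot_tracing"] = {
                "n_spots": len(spots),
                "n_frames": stack.n_frames,
                "first_bin_derivative_sd": float(prof.bin_sd[0]),
            }
            if config.plots:
                _plot_trace(stack.fluence_axis, total, prof, out / "summed_trace.png")
        except Exception as exc:
            raise type(exc)(f"[spot_tracing] {exc}") from exc

    if config.orientation_path:
        orient_path = Path(config.orientation_path)
        if not orient_path.exists():
            raise FileNotFoundError(f"orientation table not found: {orient_path}")
        summary["inputs"][str(orient_path)] = _sha256(orient_path)
        try:
            series = read_orientation_table(orient_path, point_group=config.point_group)
            ops = point_group_rotations(config.point_group)
            series = clean_series(series, sigma_k=config.sigma_k, ops=ops)
            rot = net_rotation(series)
            quake = detect_quake(rot, threshold=config.quake_threshold)
            write_orientation_table(series, out / "orientations_clean.tsv")
            np.savetxt(
                out / "rotation_curve.tsv",
                np.column_stack(
                    [rot.frame_index, rot.fluence, rot.per_frame_angle, rot.per_vector_angles]
                ),
                delimiter="\t",
                header="frame\tfluence\tangle_deg\tangle_a\tangle_b\tangle_c",
                comments="",
            )
            summary["bir"] = {
                "final_angle_deg": rot.final_angle,
                "final_axis": [float(x) for x in rot.final_axis],
                "final_fluence": rot.final_fluence,
                "n_rejected": int(np.count_nonzero(~series.valid)),
                "quake_fluence": quake,
            }
            if config.plots:
                _plot_rotation(rot, out / "rotation_curve.png")
        except ValueError as exc:
            raise ValidityError(f"[orientation] {exc}") from exc

    config.to_file(out / "config.txt")
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    return summary


def _plot_trace(fluence, total, prof, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.plot(fluence, total, color="tab:blue", label="summed intensity")
    ax2 = ax.twinx()
    mids = (prof.bin_edges[:-1] + prof.bin_edges[1:]) / 2
    ax2.bar(mids, prof.bin_sd, width=0.8 * np.diff(prof.bin_edges), color="tab:orange", alpha=0.5)
    ax.set_xlabel("fluence (e$^-$ Å$^{-2}$)")
    ax.set_ylabel("normalized intensity")
    ax2.set_ylabel("derivative SD per bin")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def _plot_rotation(rot, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.plot(rot.fluence, rot.per_frame_angle, "k-", label="net rotation")
    for j, name in enumerate("abc"):
        ax.plot(rot.fluence, rot.per_vector_angles[:, j], alpha=0.7, label=name)
    ax.set_xlabel("fluence (e$^-$ Å$^{-2}$)")
    ax.set_ylabel("angle from frame 0 (deg)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


# ---------------------------------------------------------------------------
# canonical fixtures


def make_fixtures(seed: int = 0, out_dir: str | Path = "fixtures") -> Path:
    """Write the canonical small datasets with ground-truth manifests."""
    from .synthetic import (
        BirTrajectory,
        CrystalModel,
        generate_bend_contour_stack,
        render_dose_series,
        scramble_indexing,
        simulate_orientation_track,
    )

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    model = CrystalModel(point_group="222", seed=seed)

    # drift-only orientation track, scrambled
    drift = BirTrajectory(n_frames=150, fluence_per_frame=0.01, drift_rate=1.0, jitter_sd=0.005)
    track = simulate_orientation_track(model, drift)
    scrambled = scramble_indexing(track, model, noise_sd=0.01, misindex_fraction=0.05, seed=seed + 1)
    write_orientation_table(scrambled, out / "drift_orientations.tsv")
    write_manifest(
        out / "drift_orientations.manifest",
        {
            "kind": "drift",
            "seed": seed,
            "drift_rate": drift.drift_rate,
            "final_angle": track.truth["final_angle"],
            "final_axis": track.truth["final_axis"],
            "point_group": model.point_group,
        },
    )

    # quake track
    quake = BirTrajectory(
        n_frames=60,
        fluence_per_frame=0.01,
        drift_rate=0.0,
        quake_fluence=0.08,
        quake_angle=3.0,
    )
    qtrack = simulate_orientation_track(model, quake)
    qscr = scramble_indexing(qtrack, model, noise_sd=0.005, seed=seed + 2)
    write_orientation_table(qscr, out / "quake_orientations.tsv")
    write_manifest(
        out / "quake_orientations.manifest",
        {"kind": "quake", "seed": seed, "quake_fluence": 0.08, "quake_angle": 3.0, "point_group": model.point_group},
    )

    # rendered diffraction series: decay-only, and a quake (abrupt BIR) twin
    det = DetectorGeometry(shape=(256, 256), pixel_size=0.055, distance=450.0, beamstop_radius=8.0)
    render_model = CrystalModel(
        point_group="1",
        resolution_limit=1.2,
        decay_rate=2.0,
        base_intensities=20000.0,
        seed=seed,
    )
    for name, traj in (
        ("decay_series", BirTrajectory(n_frames=60, fluence_per_frame=0.01, drift_rate=0.0)),
        (
            "bir_series",
            BirTrajectory(
                n_frames=60, fluence_per_frame=0.01, drift_rate=0.0,
                quake_fluence=0.08, quake_angle=3.0,
            ),
        ),
    ):
        track = simulate_orientation_track(render_model, traj)
        stack = render_dose_series(render_model, track, det, background=100.0)
        write_stack(
            FrameStack(
                data=np.clip(stack.data, 0, 65535).astype(np.uint16),
                exposure_per_frame=stack.exposure_per_frame,
                flux=stack.flux,
                detector=det,
            ),
            out / f"{name}.mrc",
            format="mrc",
        )
        write_manifest(
            out / f"{name}.manifest",
            {
                "kind": name.split("_")[0],
                "seed": seed,
                "decay_rate": render_model.decay_rate,
                "n_frames": traj.n_frames,
                "fluence_per_frame": traj.fluence_per_frame,
                "quake_fluence": traj.quake_fluence if traj.quake_fluence is not None else "none",
                "quake_angle": traj.quake_angle,
            },
        )

    # imaging stacks
    static_img = generate_bend_contour_stack(
        n_frames=40, shape=(96, 96), band_params={"speed": 0.0, "noise_sd": 0.5}, seed=seed
    )
    write_stack(
        FrameStack(data=static_img.data.astype(np.float32), flux=static_img.flux, exposure_per_frame=1.0),
        out / "static_imaging.mrc",
    )
    band = generate_bend_contour_stack(
        n_frames=80, shape=(96, 96), band_params={"speed": 40.0, "settle_fluence": 0.5}, seed=seed
    )
    write_stack(
        FrameStack(data=band.data.astype(np.float32), flux=band.flux, exposure_per_frame=1.0),
        out / "migrating_band.mrc",
    )
    write_manifest(
        out / "migrating_band.manifest",
        {"kind": "band", "seed": seed, "speed": 40.0, "settle_fluence": 0.5, "fluence_per_frame": 0.01},
    )
    return out
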