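"""Bragg-spot detection, intensity tracing and fluctuation metrics.

The workflow mirrors still-series dose analysis: a detection image is built
by Gaussian-smoothing each frame (1-pixel radius) and taking the pixelwise
maximum over the stack, so every reflection that lights up anywhere in the
series is visible at once; thresholded connected components give spot
centers; a diamond (L1-ball) mask of 25 pixels center-to-vertex is summed
per spot per frame to give intensity traces; the brightest 20% of traces
are summed, normalized, differentiated with respect to fluence and binned —
the spread of derivative values inside each fluence bin is the fluctuation
metric that separates dynamic reorientation from plain monotonic decay.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .frame_io import FrameStack
from .geometry import DetectorGeometry

logger = logging.getLogger(__name__)

__all__ = [
    "SpotTable",
    "IntensityTraces",
    "DerivativeProfile",
    "detection_image",
    "find_spots",
    "integrate_traces",
    "summed_trace",
    "derivative_profile",
    "fluctuation_summary",
    "diamond_offsets",
]


@dataclass
class SpotTable:
    """Detected peak centers with their integration mask size."""

    centers: np.ndarray  # (n, 2) int pixel positions (row, col)
    mask_radius: int = 25
    resolution: np.ndarray | None = None  # d-spacing per spot, Å
    ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.centers = np.atleast_2d(np.rint(np.asarray(self.centers)).astype(int))
        if self.centers.size == 0:
            self.centers = self.centers.reshape(0, 2)
        if self.mask_radius < 1:
            raise ValueError("mask_radius must be >= 1")
        if self.ids is None:
            self.ids = np.arange(len(self.centers))

    def __len__(self) -> int:
        return len(self.centers)


@dataclass
class IntensityTraces:
    """Per-reflection intensity vs fluence (rows = spots, cols = frames)."""

    values: np.ndarray
    fluence_axis: np.ndarray
    ids: np.ndarray | None = None
    normalization_state: str = "raw"
    clipped: np.ndarray | None = None  # spots whose mask hit the detector edge

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.fluence_axis = np.asarray(self.fluence_axis, dtype=float)
        if self.values.shape[1] != len(self.fluence_axis):
            raise ValueError("trace length must equal number of frames")
        if self.ids is None:
            self.ids = np.arange(self.values.shape[0])

    @property
    def n_traces(self) -> int:
        return self.values.shape[0]


@dataclass
class DerivativeProfile:
    """Finite-difference derivative of a normalized trace, binned in fluence."""

    derivative: np.ndarray  # one value per frame interval
    midpoints: np.ndarray  # fluence at interval midpoints
    bin_edges: np.ndarray
    bin_sd: np.ndarray
    bin_mean: np.ndarray


def detection_image(stack: FrameStack, sigma: float = 1.0) -> np.ndarray:
    """Gaussian-smoothed maximum-intensity projection of the stack.

    Each frame is smoothed with a one-pixel-radius Gaussian, then the
    pixelwise maximum over frames is taken (smoothing before projecting).
    The beamstop disc, if geometry is attached, is filled with the median of
    the remaining pixels so it cannot seed detections.
    """
    smoothed = ndimage.gaussian_filter(stack.data.astype(float), sigma=(0, sigma, sigma))
    proj = smoothed.max(axis=0)
    if stack.detector is not None:
        mask = stack.detector.beamstop_mask()
        proj[mask] = np.median(proj[~mask])
    return proj


def _round_half_down(x: np.ndarray) -> np.ndarray:
    """Round to nearest integer, exact .5 toward the lower index."""
    return np.ceil(np.asarray(x) - 0.5).astype(int)


def find_spots(
    det_image: np.ndarray,
    threshold_factor: float = 1.25,
    background: float | str = "auto",
    mask_radius: int = 25,
    detector: DetectorGeometry | None = None,
) -> SpotTable:
    """Threshold the detection image into a table of spot centers.

    Pixels above ``threshold_factor × background`` are grouped into
    connected components; each yields an intensity-weighted centroid,
    rounded to the nearest pixel. Components whose centroids lie closer than
    ``mask_radius`` are merged (single linkage) into one spot. Background
    ``"auto"`` is the median of the image outside the beamstop disc. When
    ``detector`` is given each spot is annotated with its d-spacing.
    """
    if threshold_factor <= 1:
        raise ValueError("threshold_factor must exceed 1")
    img = np.asarray(det_image, dtype=float)
    if background == "auto":
        if detector is not None:
            background = float(np.median(img[~detector.beamstop_mask()]))
        else:
            background = float(np.median(img))
    mask = img > threshold_factor * float(background)
    labels, n = ndimage.label(mask)
    if n == 0:
        return SpotTable(centers=np.empty((0, 2), dtype=int), mask_radius=mask_radius)
    idx = np.arange(1, n + 1)
    centroids = np.array(ndimage.center_of_mass(img, labels, idx))
    weights = np.array(ndimage.sum_labels(img, labels, idx))
    # single-linkage merge of components closer than mask_radius
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if np.linalg.norm(centroids[i] - centroids[j]) < mask_radius:
                parent[find(i)] = find(j)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    centers = []
    for members in groups.values():
        w = weights[members]
        centers.append(np.average(centroids[members], axis=0, weights=w))
    centers = _round_half_down(np.array(centers))
    order = np.lexsort((centers[:, 1], centers[:, 0]))
    centers = centers[order]
    res = None
    if detector is not None:
        res = detector.pixel_to_resolution(centers[:, 0], centers[:, 1])
    return SpotTable(centers=centers, mask_radius=mask_radius, resolution=res)


def diamond_offsets(radius: int) -> tuple[np.ndarray, np.ndarray]:
    """Row/col offsets of the diamond |dr| + |dc| <= radius (2r² + 2r + 1 px)."""
    dr, dc = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    keep = np.abs(dr) + np.abs(dc) <= radius
    return dr[keep], dc[keep]


def integrate_traces(stack: FrameStack, spots: SpotTable) -> IntensityTraces:
    """Sum counts inside each spot's diamond mask, per frame.

    Masks clipped by the detector edge are summed over the clipped region
    and flagged in ``clipped``. Where two diamonds overlap, each shared
    pixel is counted only for the spot with the nearer center (ties go to
    the lower spot index).
    """
    if len(spots) == 0:
        raise ValueError("spot table is empty")
    dr, dc = diamond_offsets(spots.mask_radius)
    dist2 = dr.astype(float) ** 2 + dc.astype(float) ** 2
    n_rows, n_cols = stack.frame_shape
    # resolve overlapping masks: nearest center owns the pixel
    owner = np.full((n_rows, n_cols), -1, dtype=int)
    best = np.full((n_rows, n_cols), np.inf)
    clipped = np.zeros(len(spots), dtype=bool)
    for s, (r, c) in enumerate(spots.centers):
        rr, cc = r + dr, c + dc
        inside = (rr >= 0) & (rr < n_rows) & (cc >= 0) & (cc < n_cols)
        if not inside.all():
            clipped[s] = True
        rr, cc, d2 = rr[inside], cc[inside], dist2[inside]
        closer = d2 < best[rr, cc]  # strict: ties stay with the lower id
        owner[rr[closer], cc[closer]] = s
        best[rr[closer], cc[closer]] = d2[closer]
    values = np.empty((len(spots), stack.n_frames))
    for s, (r, c) in enumerate(spots.centers):
        rr, cc = r + dr, c + dc
        inside = (rr >= 0) & (rr < n_rows) & (cc >= 0) & (cc < n_cols)
        rr, cc = rr[inside], cc[inside]
        owned = owner[rr, cc] == s
        values[s] = stack.data[:, rr[owned], cc[owned]].sum(axis=1)
    if clipped.any():
        logger.warning("integrate_traces: %d mask(s) clipped at detector edge", int(clipped.sum()))
    return IntensityTraces(
        values=values,
        fluence_axis=stack.fluence_axis,
        ids=spots.ids.copy(),
        clipped=clipped,
    )


def summed_trace(traces: IntensityTraces, top_fraction: float = 0.2) -> np.ndarray:
    """Normalized sum of the brightest fraction of traces.

    Brightness of a trace is its maximum value wherever in the series it
    occurs; the top ``ceil(top_fraction × n)`` traces are summed framewise
    and the sum divided by its own maximum.
    """
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must be in (0, 1]")
    if traces.n_traces == 0:
        raise ValueError("no traces to sum")
    n_sel = int(np.ceil(top_fraction * traces.n_traces))
    order = np.argsort(traces.values.max(axis=1))[::-1]
    total = traces.values[order[:n_sel]].sum(axis=0)
    peak = total.max()
    if peak <= 0:
        raise ValueError("summed trace is identically zero")
    return total / peak


def derivative_profile(
    trace: np.ndarray,
    fluence_axis: np.ndarray,
    bin_width: float = 0.1,
) -> DerivativeProfile:
    """Finite-difference derivative of a trace vs fluence, with binned SD.

    The derivative over interval i is (trace[i+1] − trace[i]) / Δfluence,
    placed at the interval midpoint; bins of ``bin_width`` start at the
    first fluence value. By construction the cumulative sum of
    derivative × Δfluence reconstructs trace − trace[0] exactly.
    """
    trace = np.asarray(trace, dtype=float)
    flu = np.asarray(fluence_axis, dtype=float)
    if len(trace) < 2:
        raise ValueError("need at least two frames for a derivative")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    dflu = np.diff(flu)
    deriv = np.diff(trace) / dflu
    mid = flu[:-1] + dflu / 2
    n_bins = max(1, int(np.ceil((flu[-1] - flu[0]) / bin_width)))
    edges = flu[0] + bin_width * np.arange(n_bins + 1)
    which = np.clip(np.searchsorted(edges, mid, side="right") - 1, 0, n_bins - 1)
    sd = np.zeros(n_bins)
    mean = np.full(n_bins, np.nan)
    for b in range(n_bins):
        vals = deriv[which == b]
        if len(vals):
            sd[b] = vals.std()
            mean[b] = vals.mean()
    return DerivativeProfile(derivative=deriv, midpoints=mid, bin_edges=edges, bin_sd=sd, bin_mean=mean)


def fluctuation_summary(profiles: list[DerivativeProfile]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-bin mean and SD of the derivative fluctuation across crystals.

    All profiles must share their binning. Returns (mean_sd, sd_of_sd,
    bin_edges); with one profile the across-crystal SD is zero.
    """
    if not profiles:
        raise ValueError("need at least one profile")
    edges = profiles[0].bin_edges
    for p in profiles[1:]:
        if len(p.bin_edges) != len(edges) or not np.allclose(p.bin_edges, edges):
            raise ValueError("profiles have mismatched fluence bins")
    stack = np.vstack([p.bin_sd for p in profiles])
    return stack.mean(axis=0), stack.std(axis=0), edges


def fit_decay_rates(
    stack: FrameStack,
    spots: SpotTable,
    traces: IntensityTraces | None = None,
    min_points: int = 10,
    snr_floor: float = 10.0,
) -> dict:
    """Resolution-scaled decay rate α from log-linear fits of each trace.

    Under the decay law I(d, D) = I0 · exp(−α D / d²) the slope of
    log(background-subtracted intensity) against fluence is −α/d², so each
    trace yields α = −slope · d². The flat background per frame is estimated
    as the median pixel outside the beamstop times the mask pixel count;
    frames are used while the net intensity stays ``snr_floor`` standard
    deviations above the background noise, and the fit is weighted by the
    approximate inverse variance of the log intensity. Returns per-spot α
    (NaN where a trace has too few usable frames) and their median as the
    combined estimate.
    """
    if spots.resolution is None:
        raise ValueError("spot table has no resolution annotation (detector geometry needed)")
    if traces is None:
        traces = integrate_traces(stack, spots)
    n_px = len(diamond_offsets(spots.mask_radius)[0])
    if stack.detector is not None:
        outside = ~stack.detector.beamstop_mask()
        bg_per_px = np.array([np.median(f[outside]) for f in stack.data])
    else:
        bg_per_px = np.array([np.median(f) for f in stack.data])
    bg = bg_per_px * n_px
    noise_sd = np.sqrt(np.maximum(bg, 1.0))
    flu = traces.fluence_axis
    alpha = np.full(traces.n_traces, np.nan)
    for s in range(traces.n_traces):
        net = traces.values[s] - bg
        ok = net > snr_floor * noise_sd
        if np.count_nonzero(ok) < min_points:
            continue
        w = net[ok] / np.sqrt(net[ok] + bg[ok])  # ~1/sigma of log(net)
        slope = np.polyfit(flu[ok], np.log(net[ok]), 1, w=w)[0]
        alpha[s] = -slope * spots.resolution[s] ** 2
    fitted = alpha[np.isfinite(alpha)]
    if len(fitted) == 0:
        raise ValueError("no trace had enough usable frames for a decay fit")
    return {"alpha_per_spot": alpha, "alpha": float(np.median(fitted)), "n_fitted": int(len(fitted))}


# ---------------------------------------------------------------------------
# tabular I/O


def write_traces(traces: IntensityTraces, path: str | Path) -> None:
    df = pd.DataFrame(traces.values, columns=[f"f{j}" for j in range(traces.values.shape[1])])
    df.insert(0, "spot", traces.ids)
    df.to_csv(path, sep="\t", index=False, float_format="%.9g")
    fl = pd.DataFrame({"fluence": traces.fluence_axis})
    fl.to_csv(Path(path).with_suffix(".fluence.tsv"), sep="\t", index=False, float_format="%.9g")


def read_traces(path: str | Path) -> IntensityTraces:
    df = pd.read_csv(path, sep="\t")
    ids = df["spot"].to_numpy()
    values = df.drop(columns="spot").to_numpy(float)
    flpath = Path(path).with_suffix(".fluence.tsv")
    if flpath.exists():
        fluence = pd.read_csv(flpath, sep="\t")["fluence"].to_numpy(float)
    else:
        fluence = np.arange(1, values.shape[1] + 1, dtype=float)
    return IntensityTraces(values=values, fluence_axis=fluence, ids=ids)
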