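"""Bend-contour migration analysis of imaging-mode stacks.

A bent nanocrystal imaged in bright field shows dark bend contours — bands
where the local lattice satisfies the Bragg condition — that migrate as the
beam relaxes or buckles the lattice. The pipeline: align successive
acquisition batches by normalized cross-correlation (integer-pixel stage
drift), bin the stack by 5 in all three dimensions, low-pass filter along
time, sample pixel values along a manually chosen line to form a seismogram
(position × time), and reduce it to a fluctuation-SD trace: at each frame,
the standard deviation over line positions of |value − temporal mean at
that position|. A static scene gives an identically zero trace.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal

from .frame_io import FrameStack

logger = logging.getLogger(__name__)

__all__ = [
    "Seismogram",
    "align_batches",
    "bin_stack",
    "temporal_lowpass",
    "line_seismogram",
    "fluctuation_trace",
]


@dataclass
class Seismogram:
    line: tuple[tuple[float, float], tuple[float, float]]
    positions: np.ndarray  # sample index along the line, binned-pixel units
    values: np.ndarray  # (n_positions, n_frames)
    fluence_axis: np.ndarray
    fluctuation_sd: np.ndarray | None = None


def _ncc_shift(a: np.ndarray, b: np.ndarray) -> tuple[tuple[int, int], float]:
    """Integer shift (dr, dc) maximizing the normalized cross-correlation.

    Circular correlation via FFT of mean-subtracted images; the returned
    coefficient is the cosine similarity at the best shift. Applying the
    shift to ``b`` aligns it to ``a``.
    """
    a = np.asarray(a, float) - np.mean(a)
    b = np.asarray(b, float) - np.mean(b)
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    if denom == 0:
        return (0, 0), 0.0
    cc = np.fft.irfft2(np.fft.rfft2(a) * np.conj(np.fft.rfft2(b)), s=a.shape) / denom
    dr, dc = np.unravel_index(np.argmax(cc), cc.shape)
    if dr > a.shape[0] // 2:
        dr -= a.shape[0]
    if dc > a.shape[1] // 2:
        dc -= a.shape[1]
    return (int(dr), int(dc)), float(cc.max())


def _shift_frame(frame: np.ndarray, dr: int, dc: int) -> np.ndarray:
    out = np.zeros_like(frame)
    rows, cols = frame.shape
    r_src = slice(max(0, -dr), min(rows, rows - dr))
    c_src = slice(max(0, -dc), min(cols, cols - dc))
    r_dst = slice(max(0, dr), min(rows, rows + dr))
    c_dst = slice(max(0, dc), min(cols, cols + dc))
    out[r_dst, c_dst] = frame[r_src, c_src]
    return out


def align_batches(batches: list[FrameStack], corr_floor: float = 0.2) -> FrameStack:
    """Concatenate acquisition batches, correcting integer-pixel stage drift.

    The shift of each batch relative to its predecessor is estimated by
    normalized cross-correlation between the last frame of one batch and
    the first frame of the next; shifts accumulate along the series. A
    correlation coefficient below ``corr_floor`` (e.g. pure noise) yields a
    zero shift with a warning. The fluence axis is rebuilt from the first
    batch's flux and exposure over the concatenated length.
    """
    if not batches:
        raise ValueError("need at least one batch")
    shapes = {b.frame_shape for b in batches}
    if len(shapes) != 1:
        raise ValueError("all batches must share the frame shape")
    first = batches[0]
    if len(batches) == 1:
        first.batch_shifts = [(0, 0)]  # type: ignore[attr-defined]
        return first
    aligned = [first.data.astype(float)]
    shifts = [(0, 0)]
    cum = (0, 0)
    for prev, cur in zip(batches, batches[1:]):
        (dr, dc), coef = _ncc_shift(prev.data[-1], cur.data[0])
        if coef < corr_floor:
            logger.warning("align_batches: correlation %.3f below floor, zero shift", coef)
            dr, dc = 0, 0
        cum = (cum[0] + dr, cum[1] + dc)
        shifts.append(cum)
        if cum == (0, 0):
            aligned.append(cur.data.astype(float))
        else:
            aligned.append(np.stack([_shift_frame(f, *cum) for f in cur.data.astype(float)]))
        logger.info("align_batches: batch shift (%d, %d), cumulative %s", dr, dc, cum)
    data = np.concatenate(aligned)
    out = FrameStack(
        data=data,
        exposure_per_frame=first.exposure_per_frame,
        flux=first.flux,
        detector=first.detector,
        temperature_label=first.temperature_label,
    )
    out.batch_shifts = shifts  # type: ignore[attr-defined]
    return out


def bin_stack(stack: FrameStack, factor: int = 5) -> FrameStack:
    """Mean-bin a stack by ``factor`` in time, rows and columns.

    Trailing frames/pixels not filling a whole bin are dropped; the fluence
    axis becomes the mean fluence of the frames in each time bin.
    """
    if factor < 1:
        raise ValueError("bin factor must be >= 1")
    if factor == 1:
        return stack
    nt, nr, nc = stack.data.shape
    t, r, c = nt // factor, nr // factor, nc // factor
    if min(t, r, c) < 1:
        raise ValueError("bin factor exceeds a stack dimension")
    d = stack.data[: t * factor, : r * factor, : c * factor].astype(float)
    d = d.reshape(t, factor, r, factor, c, factor).mean(axis=(1, 3, 5))
    flu = stack.fluence_axis[: t * factor].reshape(t, factor).mean(axis=1)
    return FrameStack(
        data=d,
        exposure_per_frame=stack.exposure_per_frame * factor,
        flux=stack.flux,
        detector=None,
        temperature_label=stack.temperature_label,
        fluence_axis=flu,
    )


def temporal_lowpass(stack: FrameStack, cutoff: float | None = None, window: int = 5) -> FrameStack:
    """Zero-phase low-pass filter along the time axis, per pixel.

    With ``cutoff`` (cycles per frame, 0 < cutoff < 0.5) a 4th-order
    Butterworth applied forward-backward; without, a centered moving
    average of ``window`` frames. Either way constants pass unchanged and
    the filter is linear.
    """
    data = stack.data.astype(float)
    if cutoff is not None:
        if not 0 < cutoff < 0.5:
            raise ValueError("cutoff must be in (0, 0.5) cycles/frame")
        b, a = signal.butter(4, cutoff / 0.5)
        padlen = 3 * (max(len(a), len(b)) - 1)
        if stack.n_frames <= padlen:
            raise ValueError(f"need more than {padlen} frames for this filter")
        out = signal.filtfilt(b, a, data, axis=0)
    else:
        out = ndimage.uniform_filter1d(data, size=window, axis=0, mode="nearest")
    return FrameStack(
        data=out,
        exposure_per_frame=stack.exposure_per_frame,
        flux=stack.flux,
        detector=stack.detector,
        temperature_label=stack.temperature_label,
        fluence_axis=stack.fluence_axis.copy(),
    )


def line_seismogram(stack: FrameStack, p0: tuple[float, float], p1: tuple[float, float]) -> Seismogram:
    """Sample the stack along a line segment for every frame.

    Bilinear interpolation, one sample per pixel of line length. Reversing
    the endpoints flips the position axis.
    """
    p0 = np.asarray(p0, float)
    p1 = np.asarray(p1, float)
    length = np.linalg.norm(p1 - p0)
    if length == 0:
        raise ValueError("line endpoints coincide")
    nr, nc = stack.frame_shape
    for p in (p0, p1):
        if not (0 <= p[0] <= nr - 1 and 0 <= p[1] <= nc - 1):
            raise ValueError("line endpoints must lie inside the image")
    n_samples = int(np.floor(length)) + 1
    ts = np.linspace(0.0, 1.0, n_samples)
    coords = p0[None, :] + ts[:, None] * (p1 - p0)[None, :]
    values = np.empty((n_samples, stack.n_frames))
    for t in range(stack.n_frames):
        values[:, t] = ndimage.map_coordinates(
            stack.data[t].astype(float), coords.T, order=1, mode="nearest"
        )
    return Seismogram(
        line=(tuple(p0), tuple(p1)),
        positions=np.arange(n_samples, dtype=float),
        values=values,
        fluence_axis=stack.fluence_axis.copy(),
    )


def fluctuation_trace(s: Seismogram) -> np.ndarray:
    """Fluctuation-SD curve of a seismogram, stored on it and returned.

    amp(pos, t) = |value(pos, t) − temporal mean at pos|; the trace is the
    SD of amp over positions at each frame. Zero for a static scene and
    invariant to adding a global constant; spatially uniform flicker also
    gives zero because the SD is taken over positions.
    """
    if s.values.shape[1] < 2:
        raise ValueError("need at least two frames")
    amp = np.abs(s.values - s.values.mean(axis=1, keepdims=True))
    s.fluctuation_sd = amp.std(axis=0)
    return s.fluctuation_sd
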