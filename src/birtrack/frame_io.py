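"""Frame-stack container and detector-image I/O.

A dose series is a 3D array of detector counts ``(frame, row, col)`` with a
cumulative-fluence axis attached: frame ``i`` carries fluence
``(i + 1) * flux * exposure_per_frame`` — the accumulated exposure at the
END of the frame, so the intensities recorded in a frame reflect all dose
delivered up to its fluence value.

Two on-disk formats are supported, both written with minimal, standard-
conformant headers:

* MRC2014 single-file stacks (modes 0, 1, 2, 6), little-endian;
* SMV (ADSC dialect) one-file-per-frame series, unsigned 16-bit.

SMV stores the beam center in millimetres with 1-based pixel origin; the
conversion to the package's 0-based (row, col) pixel convention happens
here and nowhere else.
"""

from __future__ import annotations

import re
import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .geometry import DetectorGeometry

__all__ = [
    "FrameStack",
    "read_stack",
    "write_stack",
    "calibrate_flux",
    "read_manifest",
    "write_manifest",
]


@dataclass
class FrameStack:
    """A dose series: detector counts with exposure metadata.

    ``fluence_axis`` is derived from ``flux`` and ``exposure_per_frame``
    unless given explicitly (binning in time replaces it with bin centers).
    """

    data: np.ndarray
    exposure_per_frame: float = 0.5
    flux: float = 0.01
    detector: DetectorGeometry | None = None
    temperature_label: str = "293 K"
    fluence_axis: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("stack data must be 3D (frame, row, col)")
        if self.fluence_axis is None:
            self.fluence_axis = self.default_fluence_axis()
        else:
            self.fluence_axis = np.asarray(self.fluence_axis, dtype=float)
            if len(self.fluence_axis) != self.n_frames:
                raise ValueError("fluence_axis length must equal frame count")
        if np.any(np.diff(self.fluence_axis) <= 0):
            raise ValueError("fluence_axis must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[1:]

    def default_fluence_axis(self) -> np.ndarray:
        return (np.arange(self.n_frames) + 1.0) * self.flux * self.exposure_per_frame

    def with_flux(self, flux: float) -> "FrameStack":
        """Return a copy with a new flux and a consistently recomputed axis."""
        return FrameStack(
            data=self.data,
            exposure_per_frame=self.exposure_per_frame,
            flux=flux,
            detector=self.detector,
            temperature_label=self.temperature_label,
        )


# ---------------------------------------------------------------------------
# MRC2014

_MRC_MODES = {0: np.int8, 1: np.int16, 2: np.float32, 6: np.uint16}
_MRC_MODES_INV = {np.dtype(v): k for k, v in _MRC_MODES.items()}


def _write_mrc(path: Path, data: np.ndarray) -> None:
    data = np.ascontiguousarray(data)
    if data.dtype not in _MRC_MODES_INV:
        raise ValueError(f"unsupported dtype for MRC: {data.dtype}")
    mode = _MRC_MODES_INV[data.dtype]
    nz, ny, nx = data.shape
    header = bytearray(1024)
    struct.pack_into("<10i", header, 0, nx, ny, nz, mode, 0, 0, 0, nx, ny, nz)
    struct.pack_into("<6f", header, 40, float(nx), float(ny), float(nz), 90.0, 90.0, 90.0)
    struct.pack_into("<3i", header, 64, 1, 2, 3)
    struct.pack_into("<3f", header, 76, float(data.min()), float(data.max()), float(data.mean()))
    struct.pack_into("<2i", header, 88, 0, 0)  # ispg=0 (image stack), nsymbt=0
    header[208:212] = b"MAP "
    header[212:216] = bytes([0x44, 0x44, 0, 0])  # little-endian machine stamp
    struct.pack_into("<f", header, 216, float(data.std()))
    struct.pack_into("<i", header, 220, 0)
    with open(path, "wb") as fh:
        fh.write(bytes(header))
        fh.write(data.astype(data.dtype.newbyteorder("<"), copy=False).tobytes())


def _read_mrc(path: Path) -> np.ndarray:
    with open(path, "rb") as fh:
        header = fh.read(1024)
        if len(header) < 1024:
            raise ValueError(f"{path}: truncated MRC header")
        machst = header[212]
        endian = "<" if machst in (0x44, 0x00) else ">"
        nx, ny, nz, mode = struct.unpack_from(f"{endian}4i", header, 0)
        if mode not in _MRC_MODES:
            raise ValueError(f"{path}: unsupported MRC mode {mode}")
        nsymbt = struct.unpack_from(f"{endian}i", header, 92)[0]
        fh.seek(1024 + nsymbt)
        dtype = np.dtype(_MRC_MODES[mode]).newbyteorder(endian)
        count = nx * ny * max(nz, 1)
        data = np.fromfile(fh, dtype=dtype, count=count)
    if data.size != count:
        raise ValueError(f"{path}: truncated MRC data block")
    return data.reshape(max(nz, 1), ny, nx).astype(_MRC_MODES[mode])


# ---------------------------------------------------------------------------
# SMV (ADSC dialect)

_SMV_HEADER_BYTES = 512


def _smv_header(det: DetectorGeometry | None, shape: tuple[int, int]) -> bytes:
    rows, cols = shape
    det = det or DetectorGeometry(shape=shape)
    bc_row, bc_col = det.beam_center
    fields = [
        ("HEADER_BYTES", f"{_SMV_HEADER_BYTES:4d}"),
        ("DIM", "2"),
        ("BYTE_ORDER", "little_endian"),
        ("TYPE", "unsigned_short"),
        ("SIZE1", str(cols)),
        ("SIZE2", str(rows)),
        ("PIXEL_SIZE", f"{det.pixel_size:.6f}"),
        ("BIN", "1x1"),
        ("DISTANCE", f"{det.distance:.6f}"),
        ("WAVELENGTH", f"{det.wavelength:.6f}"),
        # ADSC convention: mm, 1-based pixel origin
        ("BEAM_CENTER_X", f"{(bc_col + 1.0) * det.pixel_size:.6f}"),
        ("BEAM_CENTER_Y", f"{(bc_row + 1.0) * det.pixel_size:.6f}"),
    ]
    text = "{\n" + "".join(f"{k}={v};\n" for k, v in fields) + "}\f\n"
    raw = text.encode("ascii")
    if len(raw) > _SMV_HEADER_BYTES:
        raise ValueError("SMV header overflow")
    return raw + b" " * (_SMV_HEADER_BYTES - len(raw))


def _parse_smv_header(raw: bytes) -> dict[str, str]:
    text = raw.decode("ascii", errors="replace")
    return dict(re.findall(r"(\w+)\s*=\s*([^;]+);", text))


def _write_smv_frame(path: Path, frame: np.ndarray, det: DetectorGeometry | None) -> None:
    if np.any(frame < 0) or np.any(frame > 65535):
        raise ValueError("SMV stores unsigned 16-bit counts; frame out of range")
    with open(path, "wb") as fh:
        fh.write(_smv_header(det, frame.shape))
        fh.write(np.ascontiguousarray(frame, dtype="<u2").tobytes())


def _read_smv_frame(path: Path) -> tuple[np.ndarray, dict[str, str]]:
    with open(path, "rb") as fh:
        head = fh.read(_SMV_HEADER_BYTES)
        hdr = _parse_smv_header(head)
        nbytes = int(hdr.get("HEADER_BYTES", _SMV_HEADER_BYTES))
        if nbytes > _SMV_HEADER_BYTES:
            fh.read(nbytes - _SMV_HEADER_BYTES)
        cols, rows = int(hdr["SIZE1"]), int(hdr["SIZE2"])
        order = "<" if hdr.get("BYTE_ORDER", "little_endian").strip() == "little_endian" else ">"
        data = np.fromfile(fh, dtype=f"{order}u2", count=rows * cols)
    if data.size != rows * cols:
        raise ValueError(f"{path}: truncated SMV data block")
    return data.reshape(rows, cols).astype(np.uint16), hdr


def _smv_geometry(hdr: dict[str, str], shape: tuple[int, int]) -> DetectorGeometry | None:
    try:
        pixel = float(hdr["PIXEL_SIZE"])
        det = DetectorGeometry(
            shape=shape,
            pixel_size=pixel,
            distance=float(hdr["DISTANCE"]),
            wavelength=float(hdr["WAVELENGTH"]),
            beam_center=(
                float(hdr["BEAM_CENTER_Y"]) / pixel - 1.0,
                float(hdr["BEAM_CENTER_X"]) / pixel - 1.0,
            ),
        )
        return det
    except (KeyError, ValueError):
        return None


_NUM_SUFFIX = re.compile(r"(\d+)\.[A-Za-z]+$")


def _series_sort_key(path: Path) -> int:
    m = _NUM_SUFFIX.search(path.name)
    if not m:
        raise ValueError(f"SMV series file without numeric suffix: {path.name}")
    return int(m.group(1))


# ---------------------------------------------------------------------------
# public API


def read_stack(
    path: str | Path,
    format: str | None = None,
    *,
    exposure_per_frame: float = 0.5,
    flux: float = 0.01,
    detector: DetectorGeometry | None = None,
    temperature_label: str = "293 K",
) -> FrameStack:
    """Load a diffraction or imaging stack.

    ``format`` is ``"mrc"`` or ``"smv-series"``; inferred from the path when
    omitted (directory or ``.img`` glob → SMV series). Header-borne geometry
    (SMV) overrides the ``detector`` argument; MRC stacks carry no detector
    geometry and use the argument as-is. SMV series frames are ordered by
    their numeric filename suffix regardless of listing order.
    """
    path = Path(path)
    if format is None:
        format = "smv-series" if (path.is_dir() or path.suffix == ".img") else "mrc"
    if format == "mrc":
        data = _read_mrc(path)
    elif format == "smv-series":
        files = sorted(path.glob("*.img")) if path.is_dir() else sorted(path.parent.glob(path.name))
        if not files:
            raise FileNotFoundError(f"no SMV frames matching {path}")
        files.sort(key=_series_sort_key)
        frames, hdr = [], {}
        shape = None
        for f in files:
            frame, hdr = _read_smv_frame(f)
            if shape is None:
                shape = frame.shape
            elif frame.shape != shape:
                raise ValueError(f"inconsistent frame shape in SMV series at {f.name}")
            frames.append(frame)
        data = np.stack(frames)
        detector = _smv_geometry(hdr, data.shape[1:]) or detector
    else:
        raise ValueError(f"unknown stack format {format!r}")
    return FrameStack(
        data=data,
        exposure_per_frame=exposure_per_frame,
        flux=flux,
        detector=detector,
        temperature_label=temperature_label,
    )


def write_stack(stack: FrameStack, path: str | Path, format: str = "mrc") -> None:
    """Write a stack as a single MRC file or an SMV ``*.img`` series.

    For SMV the target is a directory; frames are named ``frame_00001.img``
    onward. Counts must fit unsigned 16-bit for SMV.
    """
    path = Path(path)
    if format == "mrc":
        data = stack.data
        if data.dtype not in _MRC_MODES_INV:
            data = data.astype(np.float32)
        _write_mrc(path, data)
    elif format == "smv-series":
        path.mkdir(parents=True, exist_ok=True)
        for i in range(stack.n_frames):
            _write_smv_frame(path / f"frame_{i + 1:05d}.img", stack.data[i], stack.detector)
    else:
        raise ValueError(f"unknown stack format {format!r}")


def calibrate_flux(
    flatfield: np.ndarray,
    counts_per_electron: float = 16.0,
    pixel_area_at_specimen: float = 1.0,
    exposure: float = 1.0,
) -> float:
    """Flux (e⁻ Å⁻² s⁻¹) from an offset-corrected flat-field exposure.

    flux = mean(counts) / counts_per_electron / pixel_area_at_specimen / exposure,
    with the area referred to the specimen plane in Å². Assumes the detector
    pedestal has already been subtracted.
    """
    if exposure <= 0 or pixel_area_at_specimen <= 0 or counts_per_electron <= 0:
        raise ValueError("counts_per_electron, area and exposure must be positive")
    return float(np.mean(flatfield)) / counts_per_electron / pixel_area_at_specimen / exposure


# ---------------------------------------------------------------------------
# manifests: flat key=value text files recording ground-truth parameters


def write_manifest(path: str | Path, params: dict) -> None:
    with open(path, "w") as fh:
        for k, v in params.items():
            if isinstance(v, (list, tuple, np.ndarray)):
                v = ",".join(repr(float(x)) for x in np.asarray(v).ravel())
            fh.write(f"{k}={v}\n")


def read_manifest(path: str | Path) -> dict:
    """Parse a key=value manifest, coercing numbers and comma vectors."""
    out: dict = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#") or "=" not in line:
            continue
        k, v = line.split("=", 1)
        v = v.strip()
        if "," in v:
            try:
                out[k.strip()] = np.array([float(x) for x in v.split(",")])
                continue
            except ValueError:
                pass
        for cast in (int, float):
            try:
                out[k.strip()] = cast(v)
                break
            except ValueError:
                continue
        else:
            out[k.strip()] = v
    return out
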