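"""Detector geometry and electron-optical helpers.

The lab frame is right-handed with the beam along +z. Pixel indices are
0-based ``(row, col)``; the beam center is stored in pixels in the same
convention. SMV's 1-based, mm-unit header convention is converted at the
file boundary in :mod:`birtrack.frame_io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# CODATA-ish constants, SI
_H = 6.62607015e-34
_M0 = 9.1093837015e-31
_E = 1.602176634e-19
_C = 2.99792458e8


def electron_wavelength(kv: float) -> float:
    """Relativistic electron wavelength in Å for an accelerating voltage in kV.

    λ = h / sqrt(2 m0 e V (1 + eV / 2 m0 c²)); 200 kV → 0.02508 Å.
    """
    v = kv * 1e3
    lam = _H / np.sqrt(2 * _M0 * _E * v * (1 + _E * v / (2 * _M0 * _C**2)))
    return float(lam * 1e10)


@dataclass
class DetectorGeometry:
    """Flat detector normal to the beam.

    Parameters
    ----------
    shape : (rows, cols) in pixels.
    pixel_size : edge length of a square pixel, mm.
    distance : crystal-to-detector distance, mm.
    wavelength : electron wavelength, Å.
    beam_center : (row, col) of the direct beam, pixels, 0-based.
    beamstop_radius : radius of the beamstop shadow, pixels.
    """

    shape: tuple[int, int] = (512, 512)
    pixel_size: float = 0.028
    distance: float = 300.0
    wavelength: float = field(default_factory=lambda: electron_wavelength(200.0))
    beam_center: tuple[float, float] | None = None
    beamstop_radius: float = 12.0

    def __post_init__(self) -> None:
        if self.beam_center is None:
            self.beam_center = ((self.shape[0] - 1) / 2.0, (self.shape[1] - 1) / 2.0)
        if min(self.shape) <= 0 or self.pixel_size <= 0 or self.distance <= 0:
            raise ValueError("detector shape, pixel_size and distance must be positive")
        if self.wavelength <= 0:
            raise ValueError("wavelength must be positive")
        r, c = self.beam_center
        if not (0 <= r < self.shape[0] and 0 <= c < self.shape[1]):
            raise ValueError("beam center must lie inside the detector")

    def beamstop_mask(self) -> np.ndarray:
        """Boolean mask, True inside the beamstop disc."""
        rr, cc = np.indices(self.shape)
        r0, c0 = self.beam_center
        return (rr - r0) ** 2 + (cc - c0) ** 2 <= self.beamstop_radius**2

    def pixel_to_resolution(self, row: np.ndarray, col: np.ndarray) -> np.ndarray:
        """d-spacing (Å) of the Bragg condition at a detector pixel."""
        r0, c0 = self.beam_center
        radius_mm = np.hypot((np.asarray(row) - r0), (np.asarray(col) - c0)) * self.pixel_size
        two_theta = np.arctan2(radius_mm, self.distance)
        with np.errstate(divide="ignore"):
            d = self.wavelength / (2.0 * np.sin(two_theta / 2.0))
        return d

    def project(self, k: np.ndarray) -> np.ndarray:
        """Project scattered wavevectors (N, 3) onto the detector.

        Returns (N, 2) array of (row, col) pixel positions; gnomonic
        projection of the unit ray onto the plane z = distance.
        """
        k = np.atleast_2d(np.asarray(k, dtype=float))
        with np.errstate(divide="ignore", invalid="ignore"):
            x_mm = self.distance * k[:, 0] / k[:, 2]
            y_mm = self.distance * k[:, 1] / k[:, 2]
        r0, c0 = self.beam_center
        row = r0 + y_mm / self.pixel_size
        col = c0 + x_mm / self.pixel_size
        return np.column_stack([row, col])
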