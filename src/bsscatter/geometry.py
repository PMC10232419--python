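"""Acquisition and beam-stopper geometry.

The correction method needs two exposures: a normal full-field radiograph
and a second one taken with a perforated high-Z plate (the "beam stopper")
between the X-ray source and the patient.  This module describes the cone
beam geometry, projects the plate's hole lattice onto the detector plane
with the appropriate magnification, and computes the dose-relevant area
fractions of the plate.

All lengths are in millimetres.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "AcquisitionGeometry",
    "BeamStopperSpec",
    "project_bs_mask",
    "projected_hole_lattice",
    "open_area_fraction",
    "blocked_area_fraction_cai",
    "penumbra_width_mm",
]


@dataclass(frozen=True)
class AcquisitionGeometry:
    """Cone-beam acquisition geometry.

    Parameters
    ----------
    sdd_mm
        Source-to-detector distance.
    sample_to_detector_mm
        Distance between the exit surface of the sample and the detector.
    bs_to_source_mm
        Distance from the source to the beam-stopper plate.  The projected
        hole pattern is magnified by ``sdd_mm / bs_to_source_mm``.
    focal_spot_mm
        Focal spot size; sets the penumbra (geometric blur) of hole edges.
    detector_rows, detector_cols
        Detector matrix size in pixels.
    pixel_mm
        Detector pixel pitch.
    """

    sdd_mm: float
    sample_to_detector_mm: float
    bs_to_source_mm: float
    focal_spot_mm: float
    detector_rows: int
    detector_cols: int
    pixel_mm: float

    def __post_init__(self) -> None:
        if not 0 < self.bs_to_source_mm <= self.sdd_mm:
            raise ValueError("beam stopper must lie between source and detector")
        if not 0 <= self.sample_to_detector_mm < self.sdd_mm:
            raise ValueError("sample_to_detector_mm out of range")
        if self.pixel_mm <= 0:
            raise ValueError("pixel_mm must be positive")
        if self.detector_rows < 1 or self.detector_cols < 1:
            raise ValueError("detector dimensions must be >= 1")
        if self.focal_spot_mm < 0:
            raise ValueError("focal_spot_mm must be nonnegative")

    @property
    def magnification(self) -> float:
        """Magnification of the beam-stopper plane onto the detector."""
        return self.sdd_mm / self.bs_to_source_mm

    def pixel_coords_mm(self) -> tuple[np.ndarray, np.ndarray]:
        """Physical (y, x) coordinates of pixel centres, origin at detector centre."""
        r = (np.arange(self.detector_rows) - (self.detector_rows - 1) / 2.0) * self.pixel_mm
        c = (np.arange(self.detector_cols) - (self.detector_cols - 1) / 2.0) * self.pixel_mm
        return r, c


@dataclass(frozen=True)
class BeamStopperSpec:
    """Perforated plate: cylindrical holes on a square lattice.

    ``transmission_fraction`` is the residual intensity through the solid
    plate.  The default 0 treats the plate as opaque; 3 mm of tungsten
    transmits a negligible fraction of a diagnostic beam.
    """

    hole_diameter_mm: float
    hole_pitch_mm: float
    plate_thickness_mm: float = 3.0
    plate_width_mm: float = 600.0
    plate_height_mm: float = 600.0
    transmission_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.hole_diameter_mm < 0:
            raise ValueError("hole_diameter_mm must be nonnegative")
        if self.hole_pitch_mm <= self.hole_diameter_mm:
            raise ValueError("hole pitch must exceed hole diameter")
        if not 0.0 <= self.transmission_fraction <= 1.0:
            raise ValueError("transmission_fraction must lie in [0, 1]")
        if self.plate_thickness_mm <= 0 or self.plate_width_mm <= 0 or self.plate_height_mm <= 0:
            raise ValueError("plate dimensions must be positive")


def open_area_fraction(bs: BeamStopperSpec) -> float:
    """Fraction of plate area occupied by holes.

    This is the fraction of the beam NOT blocked during the obstructed
    exposure and therefore the fractional extra patient dose of the second
    acquisition: (pi/4) * (d / p)^2 on a square lattice.
    """
    return math.pi / 4.0 * (bs.hole_diameter_mm / bs.hole_pitch_mm) ** 2


def blocked_area_fraction_cai(cyl_diameter_mm: float, cyl_pitch_mm: float) -> float:
    """Blocked area fraction of a lead-cylinder mesh (Cai-style blocker).

    The cylinders block the beam where they sit, so the blocked fraction is
    (pi/4) * (d / p)^2.  Used to compare the total dose of the two
    two-acquisition schemes: the perforated plate exposes ``open_area_fraction``
    of the field, the cylinder mesh exposes ``1 - blocked_area_fraction_cai``.
    """
    if not 0 < cyl_diameter_mm < cyl_pitch_mm:
        raise ValueError("require 0 < diameter < pitch")
    return math.pi / 4.0 * (cyl_diameter_mm / cyl_pitch_mm) ** 2


def penumbra_width_mm(geom: AcquisitionGeometry) -> float:
    """Geometric blur of a hole edge at the detector.

    Similar triangles with a finite focal spot:
    ``focal_spot * (sdd - bs_to_source) / bs_to_source``.  Sampling circles
    are shrunk below the projected hole radius to stay clear of this blur.
    """
    return geom.focal_spot_mm * (geom.sdd_mm - geom.bs_to_source_mm) / geom.bs_to_source_mm


def projected_hole_lattice(
    geom: AcquisitionGeometry,
    bs: BeamStopperSpec,
    offset_mm: tuple[float, float] = (0.0, 0.0),
) -> tuple[float, float, tuple[float, float]]:
    """Projected hole pattern parameters on the detector, in pixels.

    Returns ``(pitch_px, radius_px, (row_offset_px, col_offset_px))`` where
    the offsets give the lattice node nearest the detector centre relative
    to the centre of the pixel grid.
    """
    m = geom.magnification
    pitch_px = m * bs.hole_pitch_mm / geom.pixel_mm
    radius_px = m * bs.hole_diameter_mm / 2.0 / geom.pixel_mm
    off = (m * offset_mm[0] / geom.pixel_mm, m * offset_mm[1] / geom.pixel_mm)
    return pitch_px, radius_px, off


def project_bs_mask(
    geom: AcquisitionGeometry,
    bs: BeamStopperSpec,
    offset_mm: tuple[float, float] = (0.0, 0.0),
    penumbra: bool = False,
) -> np.ndarray:
    """Project the perforation pattern onto the detector grid.

    Returns a detector-resolution float image: 1 inside a projected hole
    disk, ``transmission_fraction`` (default 0) in the plate shadow, and 1
    outside the plate extent.  Hole centres form a square lattice of pitch
    ``magnification * hole_pitch_mm`` anchored at the detector centre plus
    ``offset_mm`` (offset given in the plate plane).

    With ``penumbra=True`` the binary pattern is convolved with a disk of
    the geometric penumbra width, emulating the finite focal spot.
    """
    m = geom.magnification
    pitch = m * bs.hole_pitch_mm
    if pitch < 2.0 * geom.pixel_mm:
        raise ValueError(
            f"projected hole pitch {pitch:.3g} mm is below two pixels "
            f"({2 * geom.pixel_mm:.3g} mm); pattern unresolvable"
        )
    radius = m * bs.hole_diameter_mm / 2.0
    y, x = geom.pixel_coords_mm()
    yy = y[:, None]
    xx = x[None, :]
    oy = m * offset_mm[0]
    ox = m * offset_mm[1]
    # distance to nearest lattice node, computed modulo the pitch
    ry = (yy - oy + pitch / 2.0) % pitch - pitch / 2.0
    rx = (xx - ox + pitch / 2.0) % pitch - pitch / 2.0
    in_hole = ry * ry + rx * rx <= radius * radius
    mask = np.where(in_hole, 1.0, bs.transmission_fraction)
    # outside the physical plate the beam is unobstructed
    half_h = m * bs.plate_height_mm / 2.0
    half_w = m * bs.plate_width_mm / 2.0
    outside = (np.abs(yy - oy) > half_h) | (np.abs(xx - ox) > half_w)
    mask = np.where(outside, 1.0, mask)
    if penumbra:
        w = penumbra_width_mm(geom)
        r_px = w / 2.0 / geom.pixel_mm
        if r_px > 0.5:
            yk, xk = np.ogrid[-int(r_px) : int(r_px) + 1, -int(r_px) : int(r_px) + 1]
            disk = (yk * yk + xk * xk <= r_px * r_px).astype(float)
            disk /= disk.sum()
            mask = ndimage.convolve(mask, disk, mode="nearest")
    return mask
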