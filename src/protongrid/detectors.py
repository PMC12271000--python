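"""Detector response models for GRID commissioning measurements.

Models the measurement chain used when commissioning the collimator:

* a chamber array (32 x 32 elements on a 7.6 mm pitch, 24.4 x 24.4 cm
  active area) that partial-volume averages the steep GRID dose pattern,
* a single parallel-plate chamber whose reading is compared against the
  planned dose averaged over a 9.9 mm disc on one 1 mm dose slice,
* a scintillation screen (0.5 mm pitch) reporting relative counts with a
  saturation ceiling set by its iris,
* radiochromic film calibrated by a polynomial from red-channel optical
  density to dose over 0.25–12 Gy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .grids import DoseGrid, DosePlane

__all__ = [
    "DetectorGeometry", "FilmCalibration", "resample_array",
    "chamber_partial_volume", "percent_difference", "absolute_dose_agreement",
    "fit_film_calibration", "apply_film_calibration", "scintillator_saturation",
    "MATRIXX", "LYNX",
]


@dataclass
class DetectorGeometry:
    """Planar detector array geometry (pitch and active area in mm)."""

    dims: tuple = (32, 32)
    pitch: float = 7.6
    active_area: tuple = (244.0, 244.0)
    sampling_diameter: float = 4.5   # per-element averaging disc, mm

    def __post_init__(self):
        if self.pitch <= 0:
            raise ValueError("pitch must be positive")
        for n, area in zip(self.dims, self.active_area):
            if abs(n * self.pitch - area) > self.pitch:
                raise ValueError("dims * pitch must match active area within one pitch")

    def element_positions(self, center=(0.0, 0.0)):
        """(x, y) coordinate vectors of element centers, array centered on a point."""
        nx, ny = self.dims
        x = center[0] + (np.arange(nx) - (nx - 1) / 2.0) * self.pitch
        y = center[1] + (np.arange(ny) - (ny - 1) / 2.0) * self.pitch
        return x, y


#: chamber array: 1020 chambers in a 32 x 32 arrangement, 7.6 mm pitch
MATRIXX = DetectorGeometry(dims=(32, 32), pitch=7.6, active_area=(244.0, 244.0),
                           sampling_diameter=4.5)
#: scintillation screen: 0.5 mm pitch over 30 x 30 cm
LYNX = DetectorGeometry(dims=(600, 600), pitch=0.5, active_area=(300.0, 300.0),
                        sampling_diameter=0.5)


def resample_array(plane: DosePlane, geom: DetectorGeometry,
                   center=(0.0, 0.0), oversample: float = 0.5) -> np.ndarray:
    """Detector-array reading of a dose plane.

    Each element reports the mean dose over a flat disc of the geometry's
    sampling diameter centered on the element position; the array is
    centered on ``center``.  The disc average is evaluated by bilinear
    interpolation of the plane on a sub-grid of spacing ``oversample`` mm.

    Raises if the array (including sampling discs) extends beyond the plane.
    """
    ex, ey = geom.element_positions(center)
    x, y = plane.x(), plane.y()
    r = geom.sampling_diameter / 2.0
    if (ex[0] - r < x[0] or ex[-1] + r > x[-1]
            or ey[0] - r < y[0] or ey[-1] + r > y[-1]):
        raise ValueError("detector array extends beyond the dose plane")
    interp = RegularGridInterpolator((x, y), plane.values, method="linear")

    # disc sampling offsets (pixel-center rule on the oversampling lattice)
    n = max(int(np.ceil(2 * r / oversample)), 1)
    off = (np.arange(n) - (n - 1) / 2.0) * oversample
    ox, oy = np.meshgrid(off, off, indexing="ij")
    keep = ox ** 2 + oy ** 2 <= r ** 2
    if not keep.any():
        keep = np.zeros_like(ox, dtype=bool)
        keep[n // 2, n // 2] = True
    offs = np.column_stack([ox[keep], oy[keep]])

    xx, yy = np.meshgrid(ex, ey, indexing="ij")
    centers = np.column_stack([xx.ravel(), yy.ravel()])
    pts = (centers[:, None, :] + offs[None, :, :]).reshape(-1, 2)
    vals = interp(pts).reshape(len(centers), len(offs))
    return vals.mean(axis=1).reshape(geom.dims)


def chamber_partial_volume(grid: DoseGrid, center, diameter: float = 9.9) -> float:
    """Mean planned dose over a chamber-sized disc on a single grid slice.

    Reproduces the partial-volume-averaging reference: contour a cylinder of
    9.9 mm diameter on the slice nearest the chamber position and average
    the dose over voxels whose centers fall inside the disc.  The grid is
    expected at fine (~1 mm) resolution for this comparison.
    """
    cx, cy, cz = (float(c) for c in center)
    x, y, z = grid.coords(0), grid.coords(1), grid.coords(2)
    r = diameter / 2.0
    if (cx - r < x[0] - grid.spacing[0] / 2 or cx + r > x[-1] + grid.spacing[0] / 2
            or cy - r < y[0] - grid.spacing[1] / 2 or cy + r > y[-1] + grid.spacing[1] / 2
            or cz < z[0] - grid.spacing[2] / 2 or cz > z[-1] + grid.spacing[2] / 2):
        raise ValueError("chamber disc outside the dose grid")
    k = int(np.argmin(np.abs(z - cz)))
    xx, yy = np.meshgrid(x, y, indexing="ij")
    sel = (xx - cx) ** 2 + (yy - cy) ** 2 <= r ** 2
    if not sel.any():
        raise ValueError("disc smaller than the grid spacing")
    return float(grid.values[:, :, k][sel].mean())


def percent_difference(measured: float, planned: float) -> float:
    """Measured-vs-planned difference, 100·(measured − planned)/planned, two decimals."""
    if planned <= 0:
        raise ValueError("planned dose must be positive")
    return round(100.0 * (measured - planned) / planned, 2)


def absolute_dose_agreement(measured: float, planned: float,
                            tolerance: float = 3.0) -> bool:
    """Institutional QA rule: absolute dose agreement within 3%."""
    return abs(percent_difference(measured, planned)) <= tolerance


@dataclass
class FilmCalibration:
    """Polynomial net-OD → dose calibration for radiochromic film."""

    coefficients: np.ndarray          # highest degree first (np.polyval order)
    degree: int
    dose_range: tuple = (0.25, 12.0)  # Gy
    od_range: tuple = field(default=(0.0, 1.0))

    def __call__(self, od):
        return np.polyval(self.coefficients, od)


def fit_film_calibration(od_values, dose_values, degree: int = 3,
                         dose_range=(0.25, 12.0)) -> FilmCalibration:
    """Least-squares polynomial fit of dose against red-channel optical density.

    The fitted dose(OD) curve must be strictly monotone over the sampled OD
    range, otherwise the calibration is rejected (a non-invertible curve
    cannot serve as a calibration).
    """
    od = np.asarray(od_values, dtype=float)
    dose = np.asarray(dose_values, dtype=float)
    if od.size != dose.size or od.size < degree + 1:
        raise ValueError("need at least degree+1 matched (OD, dose) points")
    coeffs = np.polyfit(od, dose, degree)
    lo, hi = od.min(), od.max()
    grid = np.linspace(lo, hi, 512)
    deriv = np.polyval(np.polyder(coeffs), grid)
    if not (np.all(deriv > 0) or np.all(deriv < 0)):
        raise ValueError("fitted dose(OD) curve is not monotone over the "
                         "calibrated range; calibration rejected")
    return FilmCalibration(coefficients=coeffs, degree=degree,
                           dose_range=tuple(dose_range), od_range=(float(lo), float(hi)))


def apply_film_calibration(cal: FilmCalibration, od_plane):
    """Convert an OD image to dose.

    Returns ``(dose, out_of_range)`` where ``out_of_range`` flags pixels
    whose converted dose falls outside the calibrated dose range (e.g. a
    13 Gy pixel against a 0.25–12 Gy calibration).  Doses are returned
    unclamped so the flag is auditable.
    """
    od = np.asarray(od_plane, dtype=float)
    dose = cal(od)
    lo, hi = cal.dose_range
    out_of_range = (dose < lo) | (dose > hi)
    return dose, out_of_range


def scintillator_saturation(dose_cgy, ceiling_cgy: float = 50.0):
    """Scintillator CCD saturation model for a given iris setting.

    An iris opening of 50% corresponds to a maximum deliverable dose of
    50 cGy; readings are clipped at the ceiling and flagged saturated.

    Returns ``(reading_cgy, saturated_mask)``.
    """
    d = np.asarray(dose_cgy, dtype=float)
    sat = d > ceiling_cgy
    return np.minimum(d, ceiling_cgy), sat
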