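"""Planning structures: divergence-matched optimization cylinders and the scoring PTV.

For SFRT planning one cylinder is threaded through each aperture channel,
its axis collinear with the hole axis extended into the phantom, and cropped
to a depth interval measured along the beam axis from the phantom entrance
surface (the plans deliver dose between 5 and 15 cm depth with isocenter at
10 cm).  A cuboid "scoring PTV" bounds all cropped cylinders with a lateral
margin for metric reporting.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .collimator import CollimatorSpec, HoleSpec, layout_holes

__all__ = [
    "CylinderPlacement", "StructureSet", "CroppedCylinder", "Cuboid",
    "generate_cylinders", "cylinder_solid", "scoring_ptv", "rasterize",
]


@dataclass
class CylinderPlacement:
    """Placement of one optimization cylinder.

    ``translation`` is the midpoint of the cropped axis segment (room frame,
    mm); ``length`` is the axial length between the two crop planes; tilts
    are in degrees and match the generating hole.  ``z_range`` stores the
    two crop-plane z coordinates (room frame).
    """

    translation: np.ndarray
    tilt_x: float
    tilt_y: float
    diameter: float
    length: float
    z_range: tuple = (0.0, 0.0)
    hole: HoleSpec | None = None

    def __post_init__(self):
        self.translation = np.asarray(self.translation, dtype=float)
        if self.diameter <= 0 or self.length <= 0:
            raise ValueError("diameter and length must be positive")

    @property
    def direction(self) -> np.ndarray:
        """Downstream unit axis vector reconstructed from the tilts."""
        ax, ay = math.radians(self.tilt_x), math.radians(self.tilt_y)
        d = np.array([math.sin(ax) * math.cos(ay), math.sin(ay),
                      -math.cos(ax) * math.cos(ay)])
        return d / np.linalg.norm(d)


class CroppedCylinder:
    """Infinite circular cylinder about an axis, cropped by two z planes."""

    def __init__(self, axis_point, direction, radius, z_range):
        self.axis_point = np.asarray(axis_point, dtype=float)
        d = np.asarray(direction, dtype=float)
        self.direction = d / np.linalg.norm(d)
        self.radius = float(radius)
        self.z_range = (min(z_range), max(z_range))

    def contains(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(points)
        rel = p - self.axis_point
        t = rel @ self.direction
        radial = rel - np.outer(t, self.direction)
        r2 = np.einsum("ij,ij->i", radial, radial)
        inside = (r2 <= self.radius ** 2)
        inside &= (p[:, 2] >= self.z_range[0]) & (p[:, 2] <= self.z_range[1])
        return inside

    def bounds(self) -> np.ndarray:
        """Conservative axis-aligned bounding box (3, 2)."""
        zlo, zhi = self.z_range
        ends = []
        for z in (zlo, zhi):
            t = (z - self.axis_point[2]) / self.direction[2]
            ends.append(self.axis_point + t * self.direction)
        ends = np.array(ends)
        r = self.radius
        lo = ends.min(axis=0) - [r, r, 0]
        hi = ends.max(axis=0) + [r, r, 0]
        lo[2], hi[2] = zlo, zhi
        return np.column_stack([lo, hi])


class Cuboid:
    """Axis-aligned box given by (3, 2) bounds."""

    def __init__(self, bounds):
        self.bnd = np.asarray(bounds, dtype=float)
        if self.bnd.shape != (3, 2) or np.any(self.bnd[:, 0] > self.bnd[:, 1]):
            raise ValueError("bounds must be (3, 2) with lo <= hi")

    def contains(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(points)
        ok = np.ones(len(p), dtype=bool)
        for a in range(3):
            ok &= (p[:, a] >= self.bnd[a, 0]) & (p[:, a] <= self.bnd[a, 1])
        return ok

    def bounds(self) -> np.ndarray:
        return self.bnd

    @property
    def extents(self) -> np.ndarray:
        return self.bnd[:, 1] - self.bnd[:, 0]


def generate_cylinders(spec: CollimatorSpec, diameter: float,
                       depth_range: tuple = (50.0, 150.0),
                       phantom_surface_z: float = 100.0,
                       holes: list[HoleSpec] | None = None) -> list[CylinderPlacement]:
    """One cropped cylinder per aperture, collinear with the hole axis.

    Depth is measured along the beam axis from the phantom entrance surface
    (at room z = ``phantom_surface_z``; deeper is smaller z), and the
    cylinders are cropped by the two transverse planes at the stated depths.

    Parameters
    ----------
    diameter : float
        Cylinder diameter in mm (the commissioning study used 5, 10, 15).
    depth_range : (float, float)
        Increasing depths (mm) of the crop planes below the surface.
    """
    d1, d2 = depth_range
    if not d2 > d1:
        raise ValueError("depth_range must be increasing")
    if diameter <= 0:
        raise ValueError("diameter must be positive")
    if holes is None:
        holes = layout_holes(spec)
    z_top = phantom_surface_z - d1     # shallow crop plane
    z_bot = phantom_surface_z - d2     # deep crop plane
    out = []
    for h in holes:
        p0 = np.array([h.center[0], h.center[1], spec.match_plane_distance])
        d = h.direction
        z_mid = 0.5 * (z_top + z_bot)
        c = p0 + (z_mid - p0[2]) / d[2] * d
        length = (d2 - d1) / abs(d[2])
        out.append(CylinderPlacement(translation=c, tilt_x=h.tilt_x,
                                     tilt_y=h.tilt_y, diameter=diameter,
                                     length=length, z_range=(z_bot, z_top),
                                     hole=h))
    return out


def cylinder_solid(placement: CylinderPlacement) -> CroppedCylinder:
    """Analytic solid for a cylinder placement."""
    return CroppedCylinder(placement.translation, placement.direction,
                           placement.diameter / 2.0, placement.z_range)


def scoring_ptv(cylinders: list[CylinderPlacement], margin: float = 5.0) -> Cuboid:
    """Axis-aligned cuboid bounding all cropped cylinders.

    Lateral (x, y) extents are the bounding box of the cylinders expanded by
    ``margin``; the depth extent equals the crop interval exactly.
    """
    if not cylinders:
        raise ValueError("empty cylinder list")
    boxes = np.array([cylinder_solid(c).bounds() for c in cylinders])
    lo = boxes[:, :, 0].min(axis=0)
    hi = boxes[:, :, 1].max(axis=0)
    lo[:2] -= margin
    hi[:2] += margin
    return Cuboid(np.column_stack([lo, hi]))


def rasterize(solid, grid) -> np.ndarray:
    """Boolean mask of a solid on a dose grid (voxel-center inclusion).

    ``grid`` is anything exposing ``origin``, ``spacing`` and either
    ``values`` or ``dims``.  A voxel is included iff its center lies inside
    the solid; the mask volume converges to the analytic volume as the
    spacing shrinks.  A solid entirely outside the grid yields an empty mask
    with a warning.
    """
    dims = grid.values.shape if hasattr(grid, "values") else tuple(grid.dims)
    xs = grid.origin[0] + grid.spacing[0] * np.arange(dims[0])
    ys = grid.origin[1] + grid.spacing[1] * np.arange(dims[1])
    zs = grid.origin[2] + grid.spacing[2] * np.arange(dims[2])
    mask = np.zeros(dims, dtype=bool)
    xx, yy = np.meshgrid(xs, ys, indexing="ij")
    for k, z in enumerate(zs):
        pts = np.column_stack([xx.ravel(), yy.ravel(), np.full(xx.size, z)])
        mask[:, :, k] = solid.contains(pts).reshape(dims[0], dims[1])
    if not mask.any():
        warnings.warn("solid does not intersect the grid: empty mask")
    return mask


@dataclass
class StructureSet:
    """Named analytic solids with their rasterized masks on a common grid."""

    grid: object
    solids: dict = field(default_factory=dict)
    masks: dict = field(default_factory=dict)

    def add(self, name: str, solid) -> np.ndarray:
        mask = rasterize(solid, self.grid)
        self.solids[name] = solid
        self.masks[name] = mask
        return mask

    def names(self):
        return list(self.solids)
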