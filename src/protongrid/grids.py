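"""Regular dose-grid containers.

All spatial quantities are in millimetres and dose in Gy.  The room frame is
right-handed with its origin at isocenter: x = crossline, y = inline, and +z
pointing upstream from isocenter toward the snout.  A voxel's stated position
is its center.

``DoseGrid`` stores a 3D volume with ``values[ix, iy, iz]``; ``DosePlane``
stores a single transverse (x, y) plane with ``values[ix, iy]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["DoseGrid", "DosePlane"]


@dataclass
class DoseGrid:
    """Regular 3D grid of absorbed dose.

    Parameters
    ----------
    origin : (3,) float
        Position (mm) of the center of voxel ``[0, 0, 0]``.
    spacing : (3,) float
        Voxel spacing (mm) along x, y, z; strictly positive.
    values : (nx, ny, nz) float array
        Absorbed dose per voxel (Gy); finite and non-negative.
    """

    origin: np.ndarray
    spacing: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.origin.shape != (3,) or self.spacing.shape != (3,):
            raise ValueError("origin and spacing must be 3-vectors")
        if np.any(self.spacing <= 0):
            raise ValueError("spacing must be strictly positive")
        if self.values.ndim != 3:
            raise ValueError("values must be a 3D array")
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("dose values must be finite and non-negative")

    @property
    def dims(self) -> tuple:
        return self.values.shape

    def coords(self, axis: int) -> np.ndarray:
        """Voxel-center coordinates (mm) along one axis (0=x, 1=y, 2=z)."""
        n = self.values.shape[axis]
        return self.origin[axis] + self.spacing[axis] * np.arange(n)

    def voxel_volume(self) -> float:
        """Volume of a single voxel in mm^3."""
        return float(np.prod(self.spacing))


@dataclass
class DosePlane:
    """Regular 2D transverse dose plane with ``values[ix, iy]``."""

    origin: np.ndarray  # (x0, y0) mm, center of pixel [0, 0]
    spacing: np.ndarray  # (dx, dy) mm
    values: np.ndarray  # (nx, ny)
    depth: float | None = field(default=None)  # depth in phantom (mm), informational

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.origin.shape != (2,) or self.spacing.shape != (2,):
            raise ValueError("origin and spacing must be 2-vectors")
        if np.any(self.spacing <= 0):
            raise ValueError("spacing must be strictly positive")
        if self.values.ndim != 2:
            raise ValueError("values must be a 2D array")

    @property
    def dims(self) -> tuple:
        return self.values.shape

    def x(self) -> np.ndarray:
        return self.origin[0] + self.spacing[0] * np.arange(self.values.shape[0])

    def y(self) -> np.ndarray:
        return self.origin[1] + self.spacing[1] * np.arange(self.values.shape[1])

    def extent(self) -> tuple:
        """(xmin, xmax, ymin, ymax) of pixel centers, mm."""
        x, y = self.x(), self.y()
        return float(x[0]), float(x[-1]), float(y[0]), float(y[-1])
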