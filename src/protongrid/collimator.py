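"""Divergence-matched GRID collimator geometry.

The collimator is a brass block pierced by a hexagonal pattern of circular
channels.  Each channel is tilted so that its axis, extended upstream, passes
through the virtual source of the scanned pencil beam ("divergence
matching"): a hole at lateral offset x (cm) on the reference face is tilted
by x · rate_x degrees about the vertical axis, and likewise in y.  The
nominal hole centers and pitches live on the *downstream* reference face of
the block — the divergence match plane, placed 195 mm from isocenter for the
default design (23.5 cm snout extension minus a 4 cm mount offset).

Frame conventions (see :mod:`protongrid.grids`): origin at isocenter,
+z upstream toward the snout.  The mesh is built in a local frame with the
reference face in the plane z = 0 and the block occupying 0 ≤ z ≤ thickness;
``place_collimator`` carries it into the room frame.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import trimesh

from .transforms import BeamGeometry, TransformMatrix, beam_transform

__all__ = [
    "CollimatorSpec", "HoleSpec", "layout_holes", "hole_direction",
    "virtual_source_distance", "build_mesh", "place_collimator",
    "layout_hole_count", "mesh_report",
]


class LayoutError(ValueError):
    """Raised when the aperture pattern does not fit on the block face."""


@dataclass
class CollimatorSpec:
    """Physical and geometric parameters of the aperture block.

    Defaults describe a 27 x 21.5 x 5 cm brass block with 77 holes of 15 mm
    diameter in 9 rows (alternating 9/8 per row), hexagonal pitches
    20.35 / 23.50 mm, and divergence rates 0.375 / 0.324 deg/cm.
    """

    face_width: float = 270.0          # mm, x extent of the block face
    face_height: float = 215.0         # mm, y extent
    thickness: float = 50.0            # mm, along the beam axis
    hole_diameter: float = 15.0        # mm, constant along each channel
    pitch_x: float = 20.35             # mm, center-to-center within a row
    pitch_y: float = 23.50             # mm, row-to-row
    n_rows: int = 9
    holes_in_full_row: int = 9
    divergence_rate_x: float = 0.375   # deg per cm of lateral offset
    divergence_rate_y: float = 0.324   # deg/cm
    match_plane_distance: float = 195.0   # mm from isocenter to the reference face
    snout_to_mount_offset: float = 40.0   # mm between snout plane and mount
    material_density: float = 8.4      # g/cm^3
    material_name: str = "Brass"

    def __post_init__(self):
        for name in ("face_width", "face_height", "thickness", "hole_diameter",
                     "pitch_x", "pitch_y", "match_plane_distance"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.hole_diameter >= min(self.pitch_x, self.pitch_y):
            raise ValueError("hole_diameter must be smaller than both pitches")
        if self.n_rows < 1 or self.holes_in_full_row < 1:
            raise ValueError("need at least one row and one hole per row")
        if self.divergence_rate_x <= 0 or self.divergence_rate_y <= 0:
            raise ValueError("divergence rates must be positive")
        span_x = (self.holes_in_full_row - 1) * self.pitch_x + self.hole_diameter
        span_y = (self.n_rows - 1) * self.pitch_y + self.hole_diameter
        if span_x > self.face_width or span_y > self.face_height:
            raise LayoutError(
                f"aperture pattern ({span_x:.1f} x {span_y:.1f} mm) does not fit "
                f"the {self.face_width:.1f} x {self.face_height:.1f} mm face")


@dataclass
class HoleSpec:
    """One aperture channel: center on the reference face, tilts, and axis.

    ``direction`` is the unit vector of the channel axis pointing downstream
    (toward the patient); extended upstream it passes through the virtual
    source.  ``tilt_x`` is the tilt toward divergence about the vertical
    axis (driven by the x offset), ``tilt_y`` about the horizontal axis.
    """

    row_index: int
    col_index: int
    center: np.ndarray           # (x, y) mm on the reference face
    tilt_x: float                # degrees
    tilt_y: float                # degrees
    direction: np.ndarray        # unit 3-vector, downstream

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)


def layout_hole_count(n_rows: int, holes_in_full_row: int) -> int:
    """Closed-form hole count: odd rows full, even rows one short."""
    return (-(-n_rows // 2)) * holes_in_full_row + (n_rows // 2) * (holes_in_full_row - 1)


def hole_direction(hole_center, spec: CollimatorSpec):
    """Channel axis and tilts for a hole centered at (x, y) mm.

    Tilt magnitudes are offset (cm) times the divergence rate (deg/cm).  The
    axis is the downstream face normal rotated by tilt_y about the x-axis,
    then by tilt_x about the y-axis, with signs chosen so every axis
    converges at the virtual source upstream (i.e. diverges toward the
    patient).

    Returns
    -------
    direction : (3,) unit vector (downstream)
    tilt_x, tilt_y : float, degrees
    """
    x, y = float(hole_center[0]), float(hole_center[1])
    tilt_x = (x / 10.0) * spec.divergence_rate_x
    tilt_y = (y / 10.0) * spec.divergence_rate_y
    ax = math.radians(tilt_x)
    ay = math.radians(tilt_y)
    # R_y(-tilt_x) @ R_x(tilt_y) @ (0, 0, -1): downstream normal tipped outward
    d = np.array([math.sin(ax) * math.cos(ay),
                  math.sin(ay),
                  -math.cos(ax) * math.cos(ay)])
    return d / np.linalg.norm(d), tilt_x, tilt_y


def layout_holes(spec: CollimatorSpec) -> list[HoleSpec]:
    """Hexagonal aperture layout on the reference face, row-major order.

    Odd rows (1st, 3rd, ...) carry ``holes_in_full_row`` holes; even rows one
    fewer, offset by half a pitch.  The pattern is centered so the middle
    hole of the middle row sits at (0, 0).
    """
    holes = []
    y0 = -(spec.n_rows - 1) / 2.0 * spec.pitch_y
    for i in range(spec.n_rows):
        full = (i % 2 == 0)
        n = spec.holes_in_full_row if full else spec.holes_in_full_row - 1
        if n < 1:
            continue
        x0 = -(n - 1) / 2.0 * spec.pitch_x
        y = y0 + i * spec.pitch_y
        for j in range(n):
            c = np.array([x0 + j * spec.pitch_x, y])
            d, tx, ty = hole_direction(c, spec)
            holes.append(HoleSpec(row_index=i, col_index=j, center=c,
                                  tilt_x=tx, tilt_y=ty, direction=d))
    return holes


def virtual_source_distance(rate: float) -> float:
    """Distance (mm) upstream of the match plane where tilted axes meet the beam axis.

    For a divergence rate in deg/cm, a hole at small offset x cm is tilted by
    x·rate degrees, so its axis crosses the beam axis 10/tan(rate·π/180) mm
    upstream.  Because the design tilts are linear in offset while exact
    convergence would require linear tangents, outer holes cross slightly
    closer (a ~0.1% effect for this block).
    """
    if rate <= 0:
        raise ValueError("divergence rate must be positive")
    return 10.0 / math.tan(math.radians(rate))


# ---------------------------------------------------------------------------
# Mesh generation
# ---------------------------------------------------------------------------

def _cell_bounds(spec: CollimatorSpec, holes: list[HoleSpec], gap: float = 0.001):
    """Tile the face into one rectangle per hole (strip per row, split at
    midpoints between neighbors; border cells extend to the face edge).

    Each cell is inset laterally by ``gap`` mm so neighboring solids never
    share exactly coincident wall vertices: coincident walls would be merged
    back together by the float32 quantization of STL round-trips.  The 2 µm
    parting planes bias the volume by ~0.05%, far inside facet tolerance."""
    rows: dict[int, list[HoleSpec]] = {}
    for h in holes:
        rows.setdefault(h.row_index, []).append(h)
    row_ids = sorted(rows)
    row_y = {i: rows[i][0].center[1] for i in row_ids}
    hw, hh = spec.face_width / 2.0, spec.face_height / 2.0
    cells = []
    for k, i in enumerate(row_ids):
        ylo = -hh if k == 0 else 0.5 * (row_y[row_ids[k - 1]] + row_y[i])
        yhi = hh if k == len(row_ids) - 1 else 0.5 * (row_y[i] + row_y[row_ids[k + 1]])
        rr = sorted(rows[i], key=lambda h: h.center[0])
        for j, h in enumerate(rr):
            xlo = -hw if j == 0 else 0.5 * (rr[j - 1].center[0] + h.center[0])
            xhi = hw if j == len(rr) - 1 else 0.5 * (h.center[0] + rr[j + 1].center[0])
            cells.append((h, (xlo + gap, xhi - gap, ylo + gap, yhi - gap)))
    return cells


def _ray_to_rect(cx, cy, cos_a, sin_a, xlo, xhi, ylo, yhi):
    """Distance from (cx, cy) along (cos_a, sin_a) to the rectangle boundary."""
    t = math.inf
    if cos_a > 1e-15:
        t = min(t, (xhi - cx) / cos_a)
    elif cos_a < -1e-15:
        t = min(t, (xlo - cx) / cos_a)
    if sin_a > 1e-15:
        t = min(t, (yhi - cy) / sin_a)
    elif sin_a < -1e-15:
        t = min(t, (ylo - cy) / sin_a)
    return t


def _cell_solid(hole: HoleSpec, bounds, spec: CollimatorSpec, facets: int):
    """Closed triangulated solid: one rectangular cell minus its tilted channel.

    Local frame: reference (downstream) face at z = 0, block in 0 ≤ z ≤ t.
    The channel is swept along the hole axis, so the upstream opening is
    displaced by thickness · tan(tilt).
    """
    xlo, xhi, ylo, yhi = bounds
    t = spec.thickness
    r = spec.hole_diameter / 2.0
    cx, cy = hole.center
    d = hole.direction
    # axis slope per unit +z (upstream); direction points downstream (dz < 0),
    # so moving upstream the opening shifts toward the beam axis
    sx, sy = d[0] / d[2], d[1] / d[2]
    cx_top = cx + sx * t
    cy_top = cy + sy * t

    corner_angles = np.array([math.atan2(yc - cy, xc - cx)
                              for xc in (xlo, xhi) for yc in (ylo, yhi)])
    uniform = np.arange(facets) * (2 * math.pi / facets) - math.pi
    # drop uniform angles that nearly coincide with a corner ray: the sliver
    # triangles they would create collapse under STL float32 quantization
    sep = np.abs(uniform[:, None] - corner_angles[None, :])
    sep = np.minimum(sep, 2 * math.pi - sep)
    uniform = uniform[sep.min(axis=1) > 1e-3]
    angles = np.sort(np.concatenate([uniform, corner_angles]))
    n = len(angles)
    ca, sa = np.cos(angles), np.sin(angles)

    peri = np.array([_ray_to_rect(cx, cy, ca[k], sa[k], xlo, xhi, ylo, yhi)
                     for k in range(n)])
    if np.any(peri <= r):
        raise RuntimeError(
            f"hole ({hole.row_index},{hole.col_index}) overlaps its cell boundary")
    bx, by = cx + peri * ca, cy + peri * sa

    # vertex blocks: circle bottom/top, perimeter bottom/top
    cb = np.column_stack([cx + r * ca, cy + r * sa, np.zeros(n)])
    ct = np.column_stack([cx_top + r * ca, cy_top + r * sa, np.full(n, t)])
    pb = np.column_stack([bx, by, np.zeros(n)])
    pt = np.column_stack([bx, by, np.full(n, t)])
    verts = np.vstack([cb, ct, pb, pt])
    iCB, iCT, iPB, iPT = 0, n, 2 * n, 3 * n

    faces = []
    for k in range(n):
        k1 = (k + 1) % n
        # top annulus (z = t, outward +z)
        faces.append([iCT + k, iPT + k, iPT + k1])
        faces.append([iCT + k, iPT + k1, iCT + k1])
        # bottom annulus (z = 0, outward -z): reversed winding
        faces.append([iCB + k, iPB + k1, iPB + k])
        faces.append([iCB + k, iCB + k1, iPB + k1])
        # outer side wall (outward away from cell)
        faces.append([iPB + k, iPB + k1, iPT + k1])
        faces.append([iPB + k, iPT + k1, iPT + k])
        # channel wall (outward toward the channel axis)
        faces.append([iCB + k1, iCB + k, iCT + k])
        faces.append([iCB + k1, iCT + k, iCT + k1])
    return verts, np.asarray(faces, dtype=np.int64)


def build_mesh(spec: CollimatorSpec, holes: list[HoleSpec] | None = None,
               facets: int = 64) -> trimesh.Trimesh:
    """Triangulated solid of the block minus its tilted channels (units mm).

    The face is tiled into one rectangular cell per aperture and each cell is
    emitted as a closed solid (annular top/bottom faces, vertical outer
    walls, tilted channel wall) separated from its neighbors by micrometre
    parting planes, so the assembly is the block to within facet tolerance
    and survives STL round-trips.  With no holes the plain cuboid is
    returned.  Every connected component is watertight with consistent
    outward orientation.

    Parameters
    ----------
    facets : int
        Number of uniformly spaced segments approximating each circle (cell
        corners are always added as extra boundary vertices).
    """
    if holes is None:
        holes = layout_holes(spec)
    if len(holes) == 0:
        box = trimesh.creation.box(extents=(spec.face_width, spec.face_height,
                                            spec.thickness))
        box.apply_translation([0, 0, spec.thickness / 2.0])
        return box
    all_v, all_f, off = [], [], 0
    for h, bounds in _cell_bounds(spec, holes):
        try:
            v, f = _cell_solid(h, bounds, spec, facets)
        except RuntimeError as exc:
            raise RuntimeError(f"meshing failed: {exc}") from exc
        all_v.append(v)
        all_f.append(f + off)
        off += len(v)
    mesh = trimesh.Trimesh(vertices=np.vstack(all_v), faces=np.vstack(all_f),
                           process=False)
    return mesh


def mesh_report(mesh: trimesh.Trimesh, spec: CollimatorSpec) -> dict:
    """Volume (mm^3) and mass estimate (kg) of a collimator mesh.

    The mass is reported, not asserted: it depends on the CAD details of the
    physical block (mount features, chamfers) that the model omits.
    """
    vol = float(mesh.volume)
    return {
        "volume_mm3": vol,
        "mass_kg": vol / 1000.0 * spec.material_density / 1000.0,
        "watertight": bool(mesh.is_watertight),
        "winding_consistent": bool(mesh.is_winding_consistent),
    }


def place_collimator(mesh: trimesh.Trimesh, geom: BeamGeometry,
                     spec: CollimatorSpec) -> trimesh.Trimesh:
    """Place a local-frame collimator mesh in the room frame.

    The reference (downstream) face lands at snout_extension −
    snout_to_mount_offset from isocenter along the beam axis (195 mm for the
    default 235 mm extension), and the whole assembly is rotated by the beam
    transform.  The collimator occupies the upstream side of that plane.
    """
    if geom.snout_extension < spec.snout_to_mount_offset:
        raise ValueError("snout_extension must be >= snout_to_mount_offset")
    z_face = geom.snout_extension - spec.snout_to_mount_offset
    shift = np.eye(4)
    shift[2, 3] = z_face
    placement = beam_transform(geom).compose(TransformMatrix(shift))
    out = mesh.copy()
    out.apply_transform(placement.m)
    return out
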