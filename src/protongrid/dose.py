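"""Synthetic GRID dose engine.

A deliberately simple analytic stand-in for a Monte Carlo treatment planning
dose: Gaussian pencil spots raster-scanned across the block, an analytic
aperture transmission map (geometric shadow projected from the per-axis
virtual sources), lateral in-phantom spreading by multiple Coulomb
scattering modelled as a depth-proportional Gaussian, and a flat depth-dose
plateau.  Peaks and valleys of a GRID field are governed by this lateral
geometry, which is exactly what collimator commissioning exercises; Bragg
physics, nuclear interactions and aperture edge scatter are intentionally
absent (see docs/methods.md).

All distances mm, doses Gy, angles degrees.  The beam travels along −z with
the phantom surface at ``phantom_surface_z`` (default 100 mm, i.e. the
isocenter sits at 10 cm depth).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .collimator import CollimatorSpec, HoleSpec, layout_holes, virtual_source_distance
from .grids import DoseGrid, DosePlane
from .transforms import BeamGeometry

__all__ = [
    "BeamModel", "spot_grid", "aperture_transmission_map", "simulate_dose",
    "extract_plane", "extract_profile", "default_grid", "single_slice_grid",
]


@dataclass
class BeamModel:
    """Parameters of the synthetic pencil-beam dose model.

    spot_sigma : lateral Gaussian sigma of an uncollimated spot at the
        collimator plane (mm).  Compact synchrocyclotrons have large spots;
        12 mm is representative of the low-energy end.
    mcs_sigma_rate : additional lateral sigma per cm of depth in phantom
        (mm/cm) from multiple Coulomb scattering.
    brass_transmission : dose fraction transmitted through full-thickness
        brass (near zero for a 5 cm block).
    plateau_dose_per_mu : open-field plateau dose per monitor unit (Gy/MU).
    spot_spacing : raster spacing of spot positions (mm).
    field_size : (x, y) extent of the spot raster (mm), set to cover the
        full aperture pattern by default.
    """

    spot_sigma: float = 12.0
    mcs_sigma_rate: float = 0.4
    brass_transmission: float = 0.005
    plateau_dose_per_mu: float = 0.002
    spot_spacing: float = 2.5
    field_size: tuple = (280.0, 230.0)

    def __post_init__(self):
        if not (0.0 <= self.brass_transmission < 1.0):
            raise ValueError("brass_transmission must be in [0, 1)")
        if self.spot_sigma <= 0 or self.spot_spacing <= 0:
            raise ValueError("spot_sigma and spot_spacing must be positive")
        if self.mcs_sigma_rate < 0:
            raise ValueError("mcs_sigma_rate must be non-negative")


def spot_grid(field_size, spacing: float) -> np.ndarray:
    """Centered raster of spot positions covering a rectangular field.

    Spots are laid on a regular grid with the given spacing, inclusive of
    both field edges: a 100 x 100 mm field at 2.5 mm spacing gives 41 x 41 =
    1681 spots (the standard cross-calibration field).

    Returns an (N, 2) array of (x, y) positions in mm.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    fx, fy = float(field_size[0]), float(field_size[1])
    nx = int(round(fx / spacing)) + 1
    ny = int(round(fy / spacing)) + 1
    x = (np.arange(nx) - (nx - 1) / 2.0) * spacing
    y = (np.arange(ny) - (ny - 1) / 2.0) * spacing
    xx, yy = np.meshgrid(x, y, indexing="ij")
    return np.column_stack([xx.ravel(), yy.ravel()])


def _source_z(spec: CollimatorSpec):
    """Per-axis virtual source z positions in the room frame."""
    zsx = spec.match_plane_distance + virtual_source_distance(spec.divergence_rate_x)
    zsy = spec.match_plane_distance + virtual_source_distance(spec.divergence_rate_y)
    return zsx, zsy


def aperture_transmission_map(spec: CollimatorSpec, plane_z: float,
                              resolution: float = 1.0,
                              transmission: float = 0.0,
                              holes: list[HoleSpec] | None = None,
                              shift=(0.0, 0.0, 0.0),
                              extent=None) -> DosePlane:
    """Geometric transmission of the collimator projected onto a transverse plane.

    Each opening is the hole disc projected from the per-axis virtual
    sources through the (possibly rigidly shifted) hole center: value 1
    inside the projected openings, ``transmission`` outside.  At the match
    plane the openings are the nominal 15 mm circles at the nominal pitches;
    downstream they magnify by similar triangles (slightly anisotropically,
    because the two transverse divergence rates differ).

    Parameters
    ----------
    plane_z : float
        Room-frame z of the map plane; must be downstream of the collimator.
    shift : (3,) float
        Rigid collimator displacement (dx, dy, dz) in mm; lateral components
        move the pattern off the source axes, dz moves the block along the
        beam and changes the projection geometry.
    extent : ((xmin, xmax), (ymin, ymax)), optional
        Map extent; defaults to the block face centered on the beam axis.
    """
    if holes is None:
        holes = layout_holes(spec)
    dx, dy, dz = (float(s) for s in shift)
    z_c = spec.match_plane_distance + dz
    if plane_z >= z_c:
        raise ValueError("plane must be downstream of the collimator")
    zsx, zsy = _source_z(spec)
    mx = (zsx - plane_z) / (zsx - z_c)
    my = (zsy - plane_z) / (zsy - z_c)
    if extent is None:
        extent = ((-spec.face_width / 2.0, spec.face_width / 2.0),
                  (-spec.face_height / 2.0, spec.face_height / 2.0))
    (x0, x1), (y0, y1) = extent
    res = np.atleast_1d(np.asarray(resolution, dtype=float))
    if res.size == 1:
        res = np.repeat(res, 2)
    xs = np.arange(x0, x1 + res[0] / 2.0, res[0])
    ys = np.arange(y0, y1 + res[1] / 2.0, res[1])
    xx, yy = np.meshgrid(xs, ys, indexing="ij")
    r = spec.hole_diameter / 2.0
    inside = np.zeros(xx.shape, dtype=bool)
    for h in holes:
        cx = (h.center[0] + dx) * mx
        cy = (h.center[1] + dy) * my
        inside |= ((xx - cx) / (r * mx)) ** 2 + ((yy - cy) / (r * my)) ** 2 <= 1.0
    vals = np.where(inside, 1.0, transmission)
    return DosePlane(origin=np.array([xs[0], ys[0]]), spacing=res.copy(),
                     values=vals)


def default_grid(spec: CollimatorSpec, phantom_depth_range=(50.0, 150.0),
                 phantom_surface_z: float = 100.0, spacing=(1.0, 1.0, 2.0),
                 lateral_margin: float = 15.0) -> DoseGrid:
    """Empty dose grid covering the projected pattern over the plateau depths."""
    zsx, zsy = _source_z(spec)
    z_lo = phantom_surface_z - phantom_depth_range[1]
    m = max((zsx - z_lo) / (zsx - spec.match_plane_distance),
            (zsy - z_lo) / (zsy - spec.match_plane_distance))
    half_x = (spec.face_width / 2.0) * m + lateral_margin
    half_y = (spec.face_height / 2.0) * m + lateral_margin
    sp = np.asarray(spacing, dtype=float)
    nx = int(2 * half_x / sp[0]) + 1
    ny = int(2 * half_y / sp[1]) + 1
    nz = int((phantom_depth_range[1] - phantom_depth_range[0]) / sp[2]) + 1
    origin = np.array([-(nx - 1) / 2.0 * sp[0], -(ny - 1) / 2.0 * sp[1], z_lo])
    return DoseGrid(origin=origin, spacing=sp, values=np.zeros((nx, ny, nz)))


def single_slice_grid(spec: CollimatorSpec, depth: float = 100.0,
                      phantom_surface_z: float = 100.0, spacing: float = 1.0,
                      lateral_margin: float = 15.0) -> DoseGrid:
    """One-slice grid at a stated depth (for planar simulations and sweeps)."""
    z = phantom_surface_z - depth
    zsx, zsy = _source_z(spec)
    m = max((zsx - z) / (zsx - spec.match_plane_distance),
            (zsy - z) / (zsy - spec.match_plane_distance))
    half_x = (spec.face_width / 2.0) * m + lateral_margin
    half_y = (spec.face_height / 2.0) * m + lateral_margin
    nx = int(2 * half_x / spacing) + 1
    ny = int(2 * half_y / spacing) + 1
    origin = np.array([-(nx - 1) / 2.0 * spacing, -(ny - 1) / 2.0 * spacing, z])
    return DoseGrid(origin=origin, spacing=np.array([spacing, spacing, 1.0]),
                    values=np.zeros((nx, ny, 1)))


def simulate_dose(spec: CollimatorSpec, beam_model: BeamModel,
                  geom: BeamGeometry | None = None,
                  phantom_depth_range=(50.0, 150.0),
                  grid: DoseGrid | None = None,
                  mu: float = 1.0,
                  phantom_surface_z: float = 100.0,
                  collimator_shift=(0.0, 0.0, 0.0),
                  spots: np.ndarray | None = None,
                  holes: list[HoleSpec] | None = None) -> DoseGrid:
    """Synthetic GRID dose on a regular grid.

    Per transverse slice inside the plateau depth range the dose is::

        MU · plateau_dose_per_mu · G_σ(z) ∗ [ F_spots · T_aperture ]

    where F is the (near-uniform) normalized raster-spot fluence, T the
    projected aperture transmission, and G a Gaussian of sigma
    ``mcs_sigma_rate`` · depth(cm).  Dose is uniform along depth apart from
    the projection magnification of the pattern, and exactly linear in MU.

    ``geom.snout_extension`` sets the collimator reference-plane distance
    (snout_extension − snout_to_mount_offset); ``collimator_shift`` applies
    an additional rigid mis-positioning of the block.
    """
    if geom is None:
        geom = BeamGeometry(snout_extension=spec.match_plane_distance
                            + spec.snout_to_mount_offset)
    if grid is None:
        grid = default_grid(spec, phantom_depth_range, phantom_surface_z)
    if holes is None:
        holes = layout_holes(spec)
    d1, d2 = phantom_depth_range
    zs = grid.coords(2)
    depths = phantom_surface_z - zs
    in_plateau = (depths >= d1) & (depths <= d2)
    if not np.any(in_plateau):
        raise ValueError("grid does not intersect the plateau depth range")

    z_mount = geom.snout_extension - spec.snout_to_mount_offset
    shift = np.asarray(collimator_shift, dtype=float)
    # a snout re-extension is the same rigid z displacement as a z shift
    shift = shift + [0.0, 0.0, z_mount - spec.match_plane_distance]

    if spots is None:
        spots = spot_grid(beam_model.field_size, beam_model.spot_spacing)
    sx = np.unique(spots[:, 0])
    sy = np.unique(spots[:, 1])
    separable = len(sx) * len(sy) == len(spots)
    sigma = beam_model.spot_sigma
    flat = math.sqrt(2 * math.pi) * sigma / beam_model.spot_spacing
    zsx, zsy = _source_z(spec)
    z_c = spec.match_plane_distance + shift[2]

    xs, ys = grid.coords(0), grid.coords(1)
    out = np.zeros(grid.values.shape)
    for k in np.nonzero(in_plateau)[0]:
        z = zs[k]
        mx = (zsx - z) / (zsx - z_c)
        my = (zsy - z) / (zsy - z_c)
        if separable:
            gx = np.exp(-0.5 * ((xs[:, None] / mx - sx[None, :]) / sigma) ** 2).sum(axis=1)
            gy = np.exp(-0.5 * ((ys[:, None] / my - sy[None, :]) / sigma) ** 2).sum(axis=1)
            fluence = np.outer(gx, gy) / flat ** 2
        else:
            xx, yy = np.meshgrid(xs / mx, ys / my, indexing="ij")
            fluence = np.zeros(xx.shape)
            for px, py in spots:
                fluence += np.exp(-0.5 * (((xx - px) ** 2 + (yy - py) ** 2) / sigma ** 2))
            fluence /= flat ** 2
        tmap = aperture_transmission_map(
            spec, z, resolution=grid.spacing[:2],
            transmission=beam_model.brass_transmission, holes=holes,
            shift=shift, extent=((xs[0], xs[-1]), (ys[0], ys[-1])))
        # the transmission map is sampled on the dose grid's own x/y lattice
        field = fluence * tmap.values[:len(xs), :len(ys)]
        sig_mm = beam_model.mcs_sigma_rate * depths[k] / 10.0
        if sig_mm > 0:
            field = ndimage.gaussian_filter(
                field, sigma=(sig_mm / grid.spacing[0], sig_mm / grid.spacing[1]),
                mode="constant", cval=0.0)
        out[:, :, k] = field
    out *= mu * beam_model.plateau_dose_per_mu
    return DoseGrid(origin=grid.origin.copy(), spacing=grid.spacing.copy(),
                    values=out)


def extract_plane(grid: DoseGrid, depth: float,
                  phantom_surface_z: float = 100.0,
                  interpolate: bool = False) -> DosePlane:
    """Transverse dose plane at a stated depth in phantom.

    Nearest voxel plane by default; with ``interpolate`` the two bracketing
    slices are linearly blended.
    """
    z = phantom_surface_z - depth
    zs = grid.coords(2)
    if z < zs.min() - grid.spacing[2] / 2 or z > zs.max() + grid.spacing[2] / 2:
        raise ValueError(f"depth {depth} mm is outside the grid")
    if interpolate and len(zs) > 1:
        f = np.clip((z - zs[0]) / (zs[-1] - zs[0]) * (len(zs) - 1), 0, len(zs) - 1)
        k0 = int(np.floor(f))
        k1 = min(k0 + 1, len(zs) - 1)
        w = f - k0
        vals = (1 - w) * grid.values[:, :, k0] + w * grid.values[:, :, k1]
    else:
        k = int(np.argmin(np.abs(zs - z)))
        vals = grid.values[:, :, k]
    return DosePlane(origin=grid.origin[:2].copy(), spacing=grid.spacing[:2].copy(),
                     values=vals.copy(), depth=depth)


def extract_profile(plane: DosePlane, axis: str = "crossline",
                    offset: float = 0.0, interpolate: bool = True):
    """1D dose profile through a plane.

    ``crossline`` runs along x at inline position y = offset; ``inline``
    runs along y at x = offset.  Linear interpolation between the two
    bracketing rows/columns by default.

    Returns (positions_mm, dose).
    """
    if axis not in ("crossline", "inline"):
        raise ValueError("axis must be 'crossline' or 'inline'")
    along, across = (0, 1) if axis == "crossline" else (1, 0)
    coords_across = (plane.x, plane.y)[across]()
    c = coords_across
    if offset < c.min() or offset > c.max():
        raise ValueError("offset outside plane")
    f = (offset - c[0]) / plane.spacing[across]
    k0 = int(np.floor(f))
    k1 = min(k0 + 1, len(c) - 1)
    w = f - k0 if interpolate else round(f) - k0
    vals = plane.values if along == 0 else plane.values.T
    prof = (1 - w) * vals[:, k0] + w * vals[:, k1]
    positions = (plane.x, plane.y)[along]()
    return positions, prof
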