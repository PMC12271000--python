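"""Synthetic dose-plane fixtures with known analytic properties.

Small planes used by the test suite and demos: a uniform plane, a linear
ramp, a GRID-like plane constructed with exactly known peak/valley doses,
and a laterally shifted copy.  All randomness comes from the seed argument.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from scipy import ndimage

from .collimator import CollimatorSpec, layout_holes
from .dose import aperture_transmission_map
from .grids import DosePlane
from .io import write_plane_txt

__all__ = ["make_uniform_plane", "make_ramp_plane", "make_grid_plane",
           "make_noisy_plane", "generate_fixtures"]


def make_uniform_plane(value: float = 1.0, n: int = 41, spacing: float = 1.0) -> DosePlane:
    half = (n - 1) / 2.0 * spacing
    return DosePlane(origin=np.array([-half, -half]),
                     spacing=np.array([spacing, spacing]),
                     values=np.full((n, n), float(value)))


def make_ramp_plane(slope: float = 0.1, intercept: float = 1.0, n: int = 41,
                    spacing: float = 1.0) -> DosePlane:
    """Dose linear in x: D = intercept + slope·x (exact under linear resampling)."""
    half = (n - 1) / 2.0 * spacing
    x = np.linspace(-half, half, n)
    vals = intercept + slope * x[:, None] + np.zeros((n, n))
    return DosePlane(origin=np.array([-half, -half]),
                     spacing=np.array([spacing, spacing]), values=vals)


def make_grid_plane(peak: float = 8.0, valley: float = 1.0,
                    spec: CollimatorSpec | None = None, plane_z: float = 0.0,
                    resolution: float = 1.0, blur_mm: float = 0.0,
                    shift=(0.0, 0.0, 0.0)) -> DosePlane:
    """GRID-like plane: exactly ``peak`` inside the projected apertures and
    ``valley`` outside, optionally blurred (which erodes the contrast the
    way in-phantom scattering does)."""
    if spec is None:
        spec = CollimatorSpec()
    holes = layout_holes(spec)
    tmap = aperture_transmission_map(spec, plane_z, resolution=resolution,
                                     transmission=0.0, holes=holes, shift=shift)
    vals = valley + (peak - valley) * tmap.values
    if blur_mm > 0:
        vals = ndimage.gaussian_filter(vals, sigma=blur_mm / resolution,
                                       mode="nearest")
    return DosePlane(origin=tmap.origin, spacing=tmap.spacing, values=vals,
                     depth=100.0)


def make_noisy_plane(base: DosePlane, noise_frac: float, seed: int) -> DosePlane:
    """Multiplicative uniform noise of ±noise_frac, seeded."""
    rng = np.random.default_rng(seed)
    factor = 1.0 + noise_frac * rng.uniform(-1.0, 1.0, size=base.values.shape)
    return DosePlane(origin=base.origin.copy(), spacing=base.spacing.copy(),
                     values=base.values * factor, depth=base.depth)


def generate_fixtures(seed: int, outdir) -> dict:
    """Write the standard fixture planes as delimited text; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spec = CollimatorSpec()
    planes = {
        "uniform": make_uniform_plane(value=2.0, n=61),
        "ramp": make_ramp_plane(slope=0.05, intercept=2.0, n=61),
        "grid": make_grid_plane(peak=8.0, valley=1.0, spec=spec, blur_mm=2.0),
        "grid_shifted": make_grid_plane(peak=8.0, valley=1.0, spec=spec,
                                        blur_mm=2.0, shift=(2.0, 0.0, 0.0)),
        "grid_noisy": make_noisy_plane(
            make_grid_plane(peak=8.0, valley=1.0, spec=spec, blur_mm=2.0),
            noise_frac=0.01, seed=seed),
    }
    paths = {}
    for name, plane in planes.items():
        p = outdir / f"{name}.txt"
        write_plane_txt(plane, p)
        paths[name] = p
    return paths
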