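"""Positional-error robustness analysis of the collimator mount.

Mechanical mounting tolerances are derived by simulating systematic
collimator displacements, scoring each displaced dose plane against a fixed
reference with the clinical gamma criteria, fitting a Gaussian to the pass
rate versus offset, and solving for the offset at which the fitted curve
crosses the institutional 90% pass-rate requirement:

    G(d) = A · exp(−(d − μ)² / (2σ²)),
    tolerance = σ · sqrt(2 · ln(A / threshold))   (half-width about μ).

Lateral (x, y) displacements misalign the aperture pattern directly and
give millimetre-scale tolerances; displacements along the beam (snout
extension) only change the projection geometry and are tolerated at the
centimetre scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .collimator import CollimatorSpec
from .dose import BeamModel, extract_plane, simulate_dose, single_slice_grid
from .gamma import GammaCriteria, gamma_2d
from .grids import DosePlane
from .transforms import BeamGeometry

__all__ = ["GaussianFit", "ShiftSeries", "shift_sweep", "fit_gamma_gaussian",
           "tolerance_at"]

_AXES = {"x": 0, "y": 1, "z": 2}


@dataclass
class GaussianFit:
    """Gaussian model of gamma pass rate versus positional offset."""

    amplitude: float      # A, % pass rate at the fitted optimum
    center: float         # μ, mm
    sigma: float          # σ, mm
    axis: str = "x"
    rmse: float = field(default=float("nan"))
    covariance: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        if not (0.0 < self.amplitude <= 100.0):
            raise ValueError("amplitude must be in (0, 100]")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")

    def __call__(self, d):
        return self.amplitude * np.exp(-((np.asarray(d, dtype=float) - self.center) ** 2)
                                       / (2.0 * self.sigma ** 2))


@dataclass
class ShiftSeries:
    """Gamma pass rate measured at a set of positional offsets along one axis."""

    axis: str
    offsets: np.ndarray   # mm
    pass_rates: np.ndarray  # %

    def __post_init__(self):
        self.offsets = np.asarray(self.offsets, dtype=float)
        self.pass_rates = np.asarray(self.pass_rates, dtype=float)
        if self.axis not in _AXES:
            raise ValueError("axis must be x, y or z")
        if len(np.unique(self.offsets)) != len(self.offsets):
            raise ValueError("offsets must be distinct")
        if np.any(self.pass_rates < 0) or np.any(self.pass_rates > 100):
            raise ValueError("pass rates must be in [0, 100]")


def shift_sweep(spec: CollimatorSpec, beam_model: BeamModel,
                geom: BeamGeometry, axis: str, offsets,
                reference_plane: DosePlane, criteria: GammaCriteria,
                depth: float = 100.0, phantom_surface_z: float = 100.0,
                grid=None, mu: float = 1.0) -> ShiftSeries:
    """Gamma pass rate versus collimator displacement along one axis.

    For each offset the collimator is rigidly displaced (x/y: transverse;
    z: along the beam, equivalent to a snout re-extension), the dose plane
    at the stated depth is re-simulated, and its gamma pass rate against
    the fixed reference plane is recorded.  The offset list must include 0
    so the series is anchored at the nominal geometry.
    """
    if axis not in _AXES:
        raise ValueError("axis must be x, y or z")
    offsets = np.asarray(offsets, dtype=float)
    if not np.any(offsets == 0.0):
        raise ValueError("offsets must include 0 (the nominal position)")
    if grid is None:
        grid = single_slice_grid(spec, depth, phantom_surface_z)
    rates = []
    for off in offsets:
        shift = np.zeros(3)
        shift[_AXES[axis]] = off
        dose = simulate_dose(spec, beam_model, geom,
                             phantom_depth_range=(depth - 1.0, depth + 1.0),
                             grid=grid, mu=mu,
                             phantom_surface_z=phantom_surface_z,
                             collimator_shift=shift)
        plane = extract_plane(dose, depth, phantom_surface_z)
        rates.append(gamma_2d(reference_plane, plane, criteria).pass_rate)
    return ShiftSeries(axis=axis, offsets=offsets, pass_rates=np.asarray(rates))


def fit_gamma_gaussian(series: ShiftSeries) -> GaussianFit:
    """Least-squares Gaussian fit of pass rate versus offset.

    Initialization: amplitude at the best measured rate, center at its
    offset, sigma at half the offset span; the amplitude is bounded at
    100%.  A constant series carries no width information and is rejected.
    """
    d = series.offsets
    r = series.pass_rates
    if len(d) < 4:
        raise ValueError("need at least 4 offsets to fit a Gaussian")
    if np.allclose(r, r[0]):
        raise ValueError("constant pass-rate series: Gaussian fit is degenerate")

    def model(x, a, mu, sig):
        return a * np.exp(-((x - mu) ** 2) / (2.0 * sig ** 2))

    span = d.max() - d.min()
    p0 = (r.max(), d[int(np.argmax(r))], span / 2.0)
    bounds = ([1e-6, d.min() - span, 1e-6], [100.0, d.max() + span, 100.0 * max(span, 1.0)])
    popt, pcov = curve_fit(model, d, r, p0=p0, bounds=bounds, maxfev=20000)
    resid = r - model(d, *popt)
    return GaussianFit(amplitude=float(popt[0]), center=float(popt[1]),
                       sigma=float(popt[2]), axis=series.axis,
                       rmse=float(np.sqrt(np.mean(resid ** 2))), covariance=pcov)


def tolerance_at(fit: GaussianFit, pass_threshold: float = 90.0) -> float:
    """Positional tolerance: half-width about the fitted center where G ≥ threshold.

    Solves A·exp(−w²/(2σ²)) = threshold for w, giving
    σ·sqrt(2·ln(A/threshold)).  Undefined when the fitted amplitude does
    not reach the threshold (the plan never passes, even perfectly
    positioned).
    """
    if pass_threshold <= 0:
        raise ValueError("pass_threshold must be positive")
    if fit.amplitude < pass_threshold:
        raise ValueError(
            f"fitted amplitude {fit.amplitude:.1f}% is below the "
            f"{pass_threshold:.0f}% requirement: tolerance undefined")
    return fit.sigma * math.sqrt(2.0 * math.log(fit.amplitude / pass_threshold))
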