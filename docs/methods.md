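# Methods

## Frame and unit conventions

Right-handed room frame with origin at isocenter: x = crossline,
y = inline, +z pointing upstream from isocenter toward the snout. All
lengths are millimetres, doses Gy, angles degrees (converted to radians
only at function boundaries). Voxel/pixel positions refer to centers.
Dose planes are `values[ix, iy]`, volumes `values[ix, iy, iz]`.

## Collimator design model

The block (default 270 × 215 × 50 mm brass, ρ = 8.4 g/cm³) carries a
hexagonal pattern of circular channels: 9 rows at pitch 23.50 mm, rows
alternating 9 and 8 holes at pitch 20.35 mm, short rows offset by half a
pitch, the whole pattern centered so the middle hole of the middle row is
on the beam axis. Nominal hole centers and pitches are defined on the
**downstream face** of the block, which is the divergence match plane
(195 mm from isocenter at the default 235 mm snout extension minus the
40 mm mount offset). Whether the nominal pitches live on the match plane
or projected to isocenter was an open choice; the downstream-face
convention was adopted because that face physically sits at the stated
match-plane distance.

Each channel keeps the 15 mm hole diameter but its axis is tilted by
`θx = x(cm)·0.375 °/cm` and `θy = y(cm)·0.324 °/cm` (rotation about the
x-axis by θy, then about the y-axis by θx; at sub-degree angles the order
affects directions by < 1e−4 rad but is fixed for determinism). Signs are
chosen so all axes converge **upstream** at the per-axis virtual sources,
`10/tan(rate·π/180)` mm above the match plane (1527.9 mm in x, 1768.4 mm
in y — the two scanning magnets sit at different heights, so the source is
astigmatic). Because the design tilts are *linear in offset* while exact
convergence would require linear *tangents*, the axes of the outermost
holes cross the beam axis up to ≈ 0.3% closer than the paraxial distance;
tests assert 0.5 mm agreement for the inner holes and 0.3% for all.

### Mesh generation

No CSG boolean engine is assumed. The face is tiled into one rectangular
cell per aperture (row strips split at midpoints between neighbors, border
cells extended to the face edge) and each cell is emitted as a closed
triangulated solid: annular top/bottom faces built by a radial mapping
from the hole circle to the cell boundary (cell corners always included as
boundary vertices; uniform angles closer than 1e−3 rad to a corner ray are
dropped to avoid sliver triangles), vertical outer walls, and the tilted
channel wall swept along the hole axis. Cells are inset laterally by 1 µm
parting planes so neighboring solids never share exactly coincident
vertices — coincident walls would be re-merged by the float32 quantization
of an STL round-trip and break the closed-component structure. Every
connected component is watertight with outward orientation; the summed
volume equals the cuboid minus the channel volumes to well within 1%
(facet default: 64 segments per circle). The mass estimate
(volume × density ≈ 18.7 kg) is *reported, never asserted*: the
manufactured block is quoted at about 16 kg, and the difference plausibly
sits in mount features and chamfers outside this model.

### Placement

The beam transform's rotation block is, in row order,
`[cosθg·cosθc, −sinθg·cosθc, sinθc; sinθg, cosθg, 0; −cosθg·sinθc,
sinθg·sinθc, cosθc]` with the isocenter translation in the fourth column;
it is a proper rotation for all angles. The cylinder placement is
implemented as the proper rotation `R_x(θy)·R_z(θx)`: the commonly printed
matrix for this placement has a sign inconsistency in its (2,1) element
and is not orthonormal; the adopted form is the nearest rigid composition
consistent with the stated per-axis divergences (a unit test pins down
that exactly that one element differs).

## Planning structures

One optimization cylinder per aperture, its axis collinear with the hole
axis extended into the phantom, cropped by two transverse planes at depths
5 and 15 cm measured along the beam axis from the phantom surface
(isocenter at 10 cm depth). Cylinder `length` is the axial distance
between the crop planes — 100.0 mm for the central channel, up to
100.28 mm for the corner channels (≈ 4.3° total tilt). The scoring PTV is
the axis-aligned bounding box of all cropped cylinders expanded laterally
by a 5 mm margin, with depth extent equal to the crop interval.
Rasterization uses the voxel-center inclusion rule on a 1 mm default grid,
matching the 1 mm dose-resolution convention used for chamber reference
values.

## Synthetic dose engine

A deliberately simple analytic stand-in for the planning system's Monte
Carlo, built to reproduce the *lateral geometry* that commissioning
analyses actually exercise:

* **Spot fluence**: Gaussian raster spots (σ = 12 mm at the collimator
  plane, 2.5 mm spacing) summed separably; the default field covers the
  whole block face so every channel sits on the flat fluence plateau. The
  10 × 10 cm cross-calibration field at 2.5 mm spacing rasterizes
  41 × 41 = 1681 spots.
* **Transmission**: geometric shadow of the apertures projected from the
  per-axis virtual sources — 1 inside the (slightly anisotropically
  magnified) openings, `brass_transmission` (default 0.005) outside.
  Thin-collimator approximation; no edge-scatter modeling. This is the
  known fidelity gap: real measurements show extra uncertainty from
  protons scattered off channel edges, which this engine cannot show.
* **In-phantom spreading**: per-slice Gaussian convolution with
  σ(z) = 0.4 mm per cm of depth (multiple Coulomb scattering scale).
* **Depth dose**: flat plateau across the 5–15 cm band, since measured
  center-to-center distances and PVDR were insensitive to proton energy;
  dose is exactly linear in MU.

Consequences reproduced by construction and asserted in tests: peak
center-to-center distances scale with depth by projection from the virtual
source (shrinking at shallow depths), and PVDR decreases strictly with
the scattering rate. Absolute PVDR values from this engine (≈ 7.6 at
isocenter with defaults) are *not* calibrated against measurement — no
acceptance number depends on the engine's defaults.

## Gamma engine

Global 2D gamma: γ(e) = min over reference positions r of
`sqrt(|r−e|²/dta² + (D_ref(r)−D_e)²/ΔD²)`, ΔD = dose_diff% of the
normalization dose (reference maximum unless explicit). Defaults 3%/3 mm,
10% low-dose threshold (50% supported for the coarse chamber array). The
threshold excludes evaluated points whose *reference* dose at that
position is below the cutoff (whether vendor software excludes reference
or evaluated sub-threshold points is not documented; reference-based
exclusion is the choice here, stated explicitly). γ ≤ 1 passes, with a
1e−9 guard absorbing interpolation round-off exactly at the boundary.

The minimum is searched over the reference interpolated bilinearly on a
sub-grid of spacing dta/10 within radius 3·dta, plus the evaluated
position itself as the zero-distance candidate (so a global k% rescaling
scores exactly k/dose_diff at the normalization point). A numba kernel
enumerates candidates in order of a distance lower bound with early
termination, making it *exactly* equivalent to brute-force enumeration on
that search set while visiting few candidates; tests assert agreement with
an independent pure-numpy exhaustive implementation to 1e−6. Gamma is
asymmetric under swapping the planes (normalization and threshold follow
the reference); a test asserts the asymmetry rather than pretending it
away.

## SFRT metrics

Cumulative DVH on 0.01 Gy bins; Dxx by linear interpolation between bin
edges (agrees with a sort-based percentile within one bin width). PVDR is
estimated as the mean dose over 4 mm sampling discs at the projected
aperture centers divided by the mean over discs at the hexagon-cell
centroids between the rows — the source publication never defines its
estimator, so this definition is recorded here and in the report metadata.
gEUD is the power mean `(mean dᵢᵃ)^(1/a)`; the exponent is a required
parameter with no clinical default (none is published for this use), a = 0
is rejected, and with any zero-dose voxel and a < 0 the limiting value 0
is returned. The report table mirrors the standard SFRT reporting columns
(D90, D50, D20, D10, D5, Dmean, PVDR, D90/D10, EUD).

## Detector models

Chamber-array elements read the mean dose over a flat 4.5 mm disc (the
per-chamber sensitive geometry is unpublished; the diameter is
configurable) on the 7.6 mm pitch of the 32 × 32 array. The single-chamber
reference is the mean dose over a 9.9 mm disc on one 1 mm slice
(partial-volume averaging); the QA decision rule is
|100·(measured − planned)/planned| ≤ 3%. Scintillator counts (0–1000) are
normalized so the maximum pixel reads 100%, with a saturation ceiling of
50 cGy modeling the 50% iris setting. Film calibration is a least-squares
polynomial from red-channel net OD to dose, valid over 0.25–12 Gy,
rejected if non-monotone over the sampled OD range; conversions outside
the calibrated dose range are flagged, not silently clamped. Film LET
under-response is documented as a limitation but not modeled.

## Robustness analysis

Shift sweeps rigidly displace the collimator (x/y transverse; z along the
beam, equivalent to a snout re-extension, implemented through the
projection geometry), re-simulate the isocenter plane, and score it
against the fixed nominal plane with the clinical gamma criteria. Pass
rate vs offset is fit by `G(d) = A·exp(−(d−μ)²/2σ²)` (initialization:
A₀ = best rate, μ₀ = its offset, σ₀ = half the span; A bounded at 100).
The positional tolerance at threshold t is the half-width **about the
fitted center μ**, `σ·sqrt(2·ln(A/t))` — not about zero. On the published
inline fit (A = 95.2%, σ = 2.70 mm) this gives 0.905 mm at t = 90%,
matching the published inline tolerance exactly; the published crossline
and longitudinal tolerances (0.818, 20.09 mm) are *not* consistent with
the closed form on their own printed fit parameters (which give 1.156 and
20.55 mm — the crossline value matches a missing factor of 2 under the
square root, the longitudinal one plausibly unrounded parameters). The
closed form is used throughout; the discrepancy is documented rather than
imitated. The caption form "2×3.45 mm²" of the published fits is read as
2σ² with σ in mm, consistent with the separately printed 1σ values.

## Problem sizes and determinism

Default simulations run on single 1 mm transverse slices (~350 × 280
pixels) so a full sweep-and-fit cycle completes in seconds; 3D runs use
2 mm depth steps over the 10 cm plateau. All randomness (noise fixtures,
synthetic replicates) flows from explicit seeds; nominal simulations are
deterministic and fixed-seed runs are byte-identical.

## What passing tests do and do not show

The synthetic engine shares the real system's geometry (projection,
magnification, hexagonal packing) but none of its transport physics
(Bragg peak, nuclear interactions, edge scatter, detector noise). Tests
therefore validate the *machinery* — layout arithmetic, rigid transforms,
gamma against brute force, DVH against sorting, fit recovery under
seeded noise, metric monotonicities — and the desk-reproducible design
numbers. They do not certify agreement with measured dose: absolute
pass-rate tables, measured SFRT metrics, and the measured PVDR ≈ 5.8
require a commercial dose engine and physical detectors and are outside
this package's scope.
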