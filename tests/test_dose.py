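"""Synthetic GRID dose engine: transmission maps, simulation, planes, profiles."""

import math

import numpy as np
import pytest

import protongrid as pg
from protongrid.dose import single_slice_grid, _source_z


class TestSpotGrid:
    def test_cross_calibration_raster(self):
        assert len(pg.spot_grid((100.0, 100.0), 2.5)) == 41 * 41

    def test_centered(self):
        s = pg.spot_grid((100.0, 100.0), 2.5)
        assert np.allclose(s.mean(axis=0), 0.0)
        assert s[:, 0].max() == pytest.approx(50.0)


class TestTransmissionMap:
    def test_match_plane_openings_nominal(self, spec):
        z = spec.match_plane_distance - 1e-9
        t = pg.aperture_transmission_map(spec, z, resolution=0.5)
        # center of the central hole open; nominal pitch midpoint blocked
        ix = np.argmin(np.abs(t.x()))
        iy = np.argmin(np.abs(t.y()))
        assert t.values[ix, iy] == 1.0
        ixm = np.argmin(np.abs(t.x() - spec.pitch_x / 2))
        assert t.values[ixm, iy] == 0.0
        # opening diameter along x at the central row is the hole diameter
        row = t.values[:, iy]
        xs = t.x()
        left = xs[(row == 1.0) & (np.abs(xs) < spec.pitch_x / 2)]
        assert left.max() - left.min() == pytest.approx(spec.hole_diameter, abs=1.0)

    def test_binary_when_opaque(self, spec):
        t = pg.aperture_transmission_map(spec, 0.0, resolution=2.0, transmission=0.0)
        assert set(np.unique(t.values)) <= {0.0, 1.0}

    def test_open_area_fraction(self, spec):
        z = spec.match_plane_distance - 1e-9
        t = pg.aperture_transmission_map(spec, z, resolution=0.25)
        frac = (t.values == 1.0).mean()
        analytic = 77 * math.pi * 7.5 ** 2 / (270.0 * 215.0)
        assert frac == pytest.approx(analytic, rel=0.02)

    def test_plane_must_be_downstream(self, spec):
        with pytest.raises(ValueError):
            pg.aperture_transmission_map(spec, spec.match_plane_distance + 1.0)


class TestSimulateDose:
    def test_transparent_collimator_flat_field(self, spec):
        # transmission -> 1 everywhere: the collimator is effectively absent
        bm_open = pg.BeamModel(brass_transmission=1.0 - 1e-12, mcs_sigma_rate=0.0)
        grid = single_slice_grid(spec, 100.0, spacing=2.0)
        dose = pg.simulate_dose(spec, bm_open, grid=grid,
                                phantom_depth_range=(99, 101), mu=100.0)
        plane = pg.extract_plane(dose, 100.0)
        # interior of the field (clear of the lateral penumbra)
        sel = (np.abs(plane.x())[:, None] < 60) & (np.abs(plane.y())[None, :] < 60)
        interior = plane.values[sel]
        expected = 100.0 * bm_open.plateau_dose_per_mu
        assert np.all(np.abs(interior / expected - 1.0) < 0.01)

    def test_zero_mu_zero_dose(self, spec, beam_model, iso_grid):
        dose = pg.simulate_dose(spec, beam_model, grid=iso_grid,
                                phantom_depth_range=(99, 101), mu=0.0)
        assert np.all(dose.values == 0.0)

    def test_linear_in_mu(self, spec, beam_model, iso_grid):
        d1 = pg.simulate_dose(spec, beam_model, grid=iso_grid,
                              phantom_depth_range=(99, 101), mu=100.0)
        d3 = pg.simulate_dose(spec, beam_model, grid=iso_grid,
                              phantom_depth_range=(99, 101), mu=300.0)
        assert np.allclose(d3.values, 3.0 * d1.values, rtol=1e-12, atol=1e-300)

    def test_single_spot_through_large_hole_is_gaussian(self):
        """One spot aimed at a single large hole: the plane dose is the
        analytic 2D Gaussian (no collimation, no blur)."""
        s = pg.CollimatorSpec(n_rows=1, holes_in_full_row=1, hole_diameter=18.0,
                              pitch_x=20.0, pitch_y=20.0)
        bm = pg.BeamModel(spot_sigma=2.0, mcs_sigma_rate=0.0,
                          brass_transmission=0.0, spot_spacing=2.5)
        grid = single_slice_grid(s, 100.0, spacing=0.5, lateral_margin=5.0)
        dose = pg.simulate_dose(s, bm, grid=grid, phantom_depth_range=(99, 101),
                                mu=1000.0, spots=np.array([[0.0, 0.0]]))
        plane = pg.extract_plane(dose, 100.0)
        zsx, zsy = _source_z(s)
        mx = zsx / (zsx - s.match_plane_distance)
        my = zsy / (zsy - s.match_plane_distance)
        flat = math.sqrt(2 * math.pi) * bm.spot_sigma / bm.spot_spacing
        xx, yy = np.meshgrid(plane.x(), plane.y(), indexing="ij")
        analytic = (1000.0 * bm.plateau_dose_per_mu / flat ** 2
                    * np.exp(-0.5 * ((xx / mx) ** 2 + (yy / my) ** 2)
                             / bm.spot_sigma ** 2))
        sel = analytic > 1e-3 * analytic.max()
        assert np.max(np.abs(plane.values[sel] - analytic[sel])) \
            < 0.005 * analytic.max()

    def test_grid_must_reach_plateau(self, spec, beam_model, iso_grid):
        with pytest.raises(ValueError):
            pg.simulate_dose(spec, beam_model, grid=iso_grid,
                             phantom_depth_range=(150.0, 160.0))


class TestPlanesAndProfiles:
    def test_uniform_plane_constant_profile(self):
        plane = pg.DosePlane(np.array([-10.0, -10.0]), np.array([1.0, 1.0]),
                             np.full((21, 21), 5.0))
        _, prof = pg.extract_profile(plane, "crossline", 0.0)
        assert np.allclose(prof, 5.0)

    def test_crossline_peaks_at_projected_centers(self, spec, iso_plane, holes):
        zsx, _ = _source_z(spec)
        mx = zsx / (zsx - spec.match_plane_distance)
        expected = sorted(h.center[0] * mx for h in holes if h.row_index == 4)
        xs, prof = pg.extract_profile(iso_plane, "crossline", 0.0)
        # local maxima of the central-row profile
        locmax = np.nonzero((prof[1:-1] > prof[:-2]) & (prof[1:-1] >= prof[2:])
                            & (prof[1:-1] > 0.5 * prof.max()))[0] + 1
        found = xs[locmax]
        assert len(found) == len(expected)
        assert np.all(np.abs(found - np.asarray(expected)) <= 0.5 * iso_plane.spacing[0]
                      + 1e-9)

    def test_inline_peak_count_matches_column(self, spec, iso_plane, holes):
        ys, prof = pg.extract_profile(iso_plane, "inline", 0.0)
        locmax = np.nonzero((prof[1:-1] > prof[:-2]) & (prof[1:-1] >= prof[2:])
                            & (prof[1:-1] > 0.5 * prof.max()))[0] + 1
        n_column = sum(1 for h in holes if abs(h.center[0]) < 1e-9)
        assert len(locmax) == n_column

    def test_depth_outside_grid(self, spec, beam_model, iso_grid):
        dose = pg.simulate_dose(spec, beam_model, grid=iso_grid,
                                phantom_depth_range=(99, 101), mu=10.0)
        with pytest.raises(ValueError):
            pg.extract_plane(dose, 140.0)


class TestDepthScaling:
    def test_peak_spacing_scales_with_depth(self, spec, beam_model):
        """Center-to-center peak distances shrink at shallow depths and grow
        at deep ones, per projection from the virtual source."""
        zsx, _ = _source_z(spec)

        def central_row_peak_spacing(depth):
            grid = single_slice_grid(spec, depth, spacing=0.5)
            dose = pg.simulate_dose(spec, beam_model, grid=grid,
                                    phantom_depth_range=(depth - 1, depth + 1),
                                    mu=1000.0)
            plane = pg.extract_plane(dose, depth)
            xs, prof = pg.extract_profile(plane, "crossline", 0.0)
            locmax = np.nonzero((prof[1:-1] > prof[:-2]) & (prof[1:-1] >= prof[2:])
                                & (prof[1:-1] > 0.5 * prof.max()))[0] + 1
            return np.diff(xs[locmax]).mean()

        shallow = central_row_peak_spacing(60.0)
        deep = central_row_peak_spacing(140.0)
        for depth, measured in ((60.0, shallow), (140.0, deep)):
            z = 100.0 - depth
            expect = spec.pitch_x * (zsx - z) / (zsx - spec.match_plane_distance)
            assert measured == pytest.approx(expect, abs=0.3)
        assert deep > shallow
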