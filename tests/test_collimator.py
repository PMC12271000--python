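"""Aperture layout, channel tilts, virtual-source geometry and the block mesh."""

import math

import numpy as np
import pytest
import trimesh
from hypothesis import given, settings, strategies as st

import protongrid as pg
from protongrid.collimator import LayoutError, layout_hole_count, mesh_report


class TestLayout:
    def test_default_layout_counts(self, spec, holes):
        assert len(holes) == 77
        rows = {}
        for h in holes:
            rows.setdefault(h.row_index, []).append(h)
        assert len(rows) == 9
        counts = [len(rows[i]) for i in sorted(rows)]
        assert counts == [9, 8, 9, 8, 9, 8, 9, 8, 9]

    def test_pattern_centered_and_bbox(self, spec, holes):
        xs = np.array([h.center[0] for h in holes])
        ys = np.array([h.center[1] for h in holes])
        # middle hole of the middle row at the origin
        assert any(abs(h.center[0]) < 1e-9 and abs(h.center[1]) < 1e-9 for h in holes)
        assert xs.max() - xs.min() == pytest.approx(8 * 20.35)
        assert ys.max() - ys.min() == pytest.approx(8 * 23.50)

    def test_short_rows_offset_by_half_pitch(self, spec, holes):
        full = sorted(h.center[0] for h in holes if h.row_index == 0)
        short = sorted(h.center[0] for h in holes if h.row_index == 1)
        assert short[0] - full[0] == pytest.approx(spec.pitch_x / 2.0)

    def test_single_hole_degenerate(self):
        s = pg.CollimatorSpec(n_rows=1, holes_in_full_row=1)
        hs = pg.layout_holes(s)
        assert len(hs) == 1
        assert np.allclose(hs[0].center, [0.0, 0.0])

    def test_layout_does_not_fit_raises(self):
        with pytest.raises(LayoutError):
            pg.CollimatorSpec(face_width=150.0)  # 9 holes need 177.8 mm

    @given(n_rows=st.integers(1, 10), full=st.integers(2, 9))
    @settings(max_examples=40, derandomize=True, deadline=None)
    def test_count_formula_matches_enumeration(self, n_rows, full):
        s = pg.CollimatorSpec(face_width=400.0, face_height=400.0,
                              n_rows=n_rows, holes_in_full_row=full)
        assert len(pg.layout_holes(s)) == layout_hole_count(n_rows, full)
        assert layout_hole_count(n_rows, full) == sum(
            full if i % 2 == 0 else full - 1 for i in range(n_rows))


class TestHoleDirection:
    def test_on_axis_hole_untilted(self, spec):
        d, tx, ty = pg.hole_direction((0.0, 0.0), spec)
        assert tx == 0.0 and ty == 0.0
        assert np.allclose(d, [0.0, 0.0, -1.0])

    def test_tilts_scale_with_printed_rates(self, spec):
        _, tx, _ = pg.hole_direction((20.35, 0.0), spec)
        assert tx == pytest.approx(2.035 * 0.375)   # 0.763 deg
        _, _, ty = pg.hole_direction((0.0, 23.50), spec)
        assert ty == pytest.approx(2.350 * 0.324)   # 0.761 deg

    def test_directions_unit_and_diverging(self, spec, holes):
        for h in holes:
            assert np.linalg.norm(h.direction) == pytest.approx(1.0, abs=1e-12)
            # downstream direction tips away from the axis (divergent beam)
            assert h.direction[0] * h.center[0] >= 0
            assert h.direction[1] * h.center[1] >= 0
            assert h.direction[2] < 0

    def test_axes_converge_at_virtual_source(self, spec, holes):
        """Extended upstream, each axis crosses the beam axis near the
        per-axis virtual source; linear tilts leave a small (<0.2%)
        offset-dependent drift relative to the paraxial distance."""
        vsd_x = pg.virtual_source_distance(spec.divergence_rate_x)
        vsd_y = pg.virtual_source_distance(spec.divergence_rate_y)
        for h in holes:
            for axis, vsd in ((0, vsd_x), (1, vsd_y)):
                c = h.center[axis]
                if abs(c) < 1e-9:
                    continue
                # upstream crossing of the component plane: distance above face
                dz = abs(c / h.direction[axis] * h.direction[2])
                assert dz == pytest.approx(vsd, rel=3e-3)
                if np.hypot(*h.center) <= 30.0:
                    assert dz == pytest.approx(vsd, abs=0.5)


class TestVirtualSource:
    def test_closed_forms(self):
        assert pg.virtual_source_distance(0.375) == pytest.approx(1527.9, abs=0.05)
        assert pg.virtual_source_distance(0.324) == pytest.approx(1768.4, abs=0.05)

    def test_small_angle_limit(self):
        for rate in (0.375, 0.324):
            approx = 10.0 / math.radians(rate)
            assert pg.virtual_source_distance(rate) == pytest.approx(approx, rel=1e-4)

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(ValueError):
            pg.virtual_source_distance(0.0)


class TestMesh:
    def test_cuboid_without_holes(self, spec):
        m = pg.build_mesh(spec, holes=[])
        assert m.volume == pytest.approx(270 * 215 * 50, rel=1e-9)

    def test_watertight_and_volume(self, spec, holes, default_mesh):
        assert default_mesh.is_watertight
        assert default_mesh.is_winding_consistent
        cuboid = spec.face_width * spec.face_height * spec.thickness
        channels = sum(math.pi * (spec.hole_diameter / 2) ** 2
                       * spec.thickness / abs(h.direction[2]) for h in holes)
        assert default_mesh.volume < cuboid
        assert default_mesh.volume == pytest.approx(cuboid - channels, rel=0.01)

    def test_independent_validator(self, default_mesh):
        """Re-ingest raw vertex/face arrays through a fresh mesh object."""
        m2 = trimesh.Trimesh(vertices=default_mesh.vertices.copy(),
                             faces=default_mesh.faces.copy(), process=False)
        assert m2.is_watertight and m2.is_winding_consistent
        assert m2.volume == pytest.approx(default_mesh.volume)

    def test_mass_reported_not_asserted(self, spec, default_mesh):
        rep = mesh_report(default_mesh, spec)
        assert rep["mass_kg"] == pytest.approx(
            default_mesh.volume * 8.4e-6, rel=1e-12)
        assert "watertight" in rep

    def test_facet_refinement_converges(self, spec):
        s = pg.CollimatorSpec(n_rows=1, holes_in_full_row=1)
        hs = pg.layout_holes(s)
        coarse = pg.build_mesh(s, hs, facets=16).volume
        fine = pg.build_mesh(s, hs, facets=128).volume
        exact = s.face_width * s.face_height * s.thickness \
            - math.pi * 7.5 ** 2 * s.thickness
        assert abs(fine - exact) < abs(coarse - exact)


class TestPlacement:
    def test_reference_face_distance(self, spec, default_mesh):
        geom = pg.BeamGeometry(snout_extension=235.0)
        placed = pg.place_collimator(default_mesh, geom, spec)
        # downstream face (min z in local frame) lands at 195 mm
        assert placed.vertices[:, 2].min() == pytest.approx(195.0, abs=1e-9)

    def test_zero_net_offset_face_at_isocenter(self, spec, default_mesh):
        geom = pg.BeamGeometry(snout_extension=spec.snout_to_mount_offset)
        placed = pg.place_collimator(default_mesh, geom, spec)
        assert placed.vertices[:, 2].min() == pytest.approx(0.0, abs=1e-9)

    def test_short_snout_rejected(self, spec, default_mesh):
        with pytest.raises(ValueError):
            pg.place_collimator(default_mesh, pg.BeamGeometry(snout_extension=10.0),
                                spec)

    def test_opposed_gantry_angles_mirror(self, spec):
        m = pg.build_mesh(pg.CollimatorSpec(n_rows=1, holes_in_full_row=1),
                          pg.layout_holes(pg.CollimatorSpec(n_rows=1,
                                                            holes_in_full_row=1)))
        a = pg.place_collimator(m, pg.BeamGeometry(gantry_angle=0.0), spec)
        b = pg.place_collimator(m, pg.BeamGeometry(gantry_angle=180.0), spec)
        # 180 deg gantry rotation about z: (x, y, z) -> (-x, -y, z)
        flipped = a.vertices * np.array([-1.0, -1.0, 1.0])
        assert np.allclose(np.sort(flipped.round(9), axis=0),
                           np.sort(b.vertices.round(9), axis=0))
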