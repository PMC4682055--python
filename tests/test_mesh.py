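"""Geometry and topology of the polygonal tiling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from chiralsheet.mesh import (
    A7_BORDER,
    INNER_BORDER,
    LOWER_BORDER,
    UPPER_BORDER,
    APFrame,
    TissueMesh,
    build_annulus_mesh,
    build_hexagonal_sheet,
    cell_area,
    cell_perimeter,
    edge_angle,
    fold_angle_deg,
    load_mesh,
    save_mesh,
    validate_mesh,
)


class TestHexagonalSheet:
    def test_single_hexagon(self):
        mesh = build_hexagonal_sheet(1, 1, 1.0)
        assert (mesh.n_faces, mesh.n_vertices, mesh.n_junctions) == (1, 6, 6)
        assert validate_mesh(mesh) == []

    def test_2x2_patch_matches_hand_enumeration(self):
        # A 2x2 offset patch has 5 adjacent hexagon pairs (each sharing one
        # edge and two vertices) and two points where three cells meet:
        # 24 corners collapse to 16 vertices, 24 edges to 19.
        mesh = build_hexagonal_sheet(2, 2, 1.0)
        assert (mesh.n_vertices, mesh.n_junctions, mesh.n_faces) == (16, 19, 4)

    @settings(max_examples=20, deadline=None)
    @given(rows=st.integers(1, 4), cols=st.integers(1, 4))
    def test_euler_relation_patch(self, rows, cols):
        mesh = build_hexagonal_sheet(rows, cols, 0.8)
        assert mesh.n_vertices - mesh.n_junctions + mesh.n_faces == 1
        assert validate_mesh(mesh) == []

    @settings(max_examples=10, deadline=None)
    @given(rows=st.integers(1, 4), cols=st.integers(3, 6))
    def test_euler_relation_periodic_strip(self, rows, cols):
        mesh = build_hexagonal_sheet(rows, cols, 0.8, periodic_x=True)
        assert mesh.n_vertices - mesh.n_junctions + mesh.n_faces == 0
        assert validate_mesh(mesh) == []

    def test_border_tagging(self):
        mesh = build_hexagonal_sheet(3, 4, 1.0)
        assert np.any(mesh.role == UPPER_BORDER)
        assert np.any(mesh.role == LOWER_BORDER)
        upper_y = mesh.positions[mesh.role == UPPER_BORDER, 1]
        lower_y = mesh.positions[mesh.role == LOWER_BORDER, 1]
        assert upper_y.min() > lower_y.max()

    def test_rejects_bad_arguments(self):
        with pytest.raises(ValueError):
            build_hexagonal_sheet(0, 3, 1.0)
        with pytest.raises(ValueError):
            build_hexagonal_sheet(2, 2, -1.0)


class TestAnnulusMesh:
    def test_vertex_radii_within_circles(self):
        mesh = build_annulus_mesh(6.0, 10.0, 4, 40)
        r = np.linalg.norm(mesh.positions, axis=1)
        assert np.all(r >= 6.0 - 1e-9) and np.all(r <= 10.0 + 1e-9)

    def test_total_area_close_to_annulus(self):
        mesh = build_annulus_mesh(6.0, 10.0, 4, 40)
        exact = np.pi * (10.0**2 - 6.0**2)
        assert abs(mesh.face_areas().sum() - exact) / exact < 0.05

    def test_outer_ring_passive_and_tagged(self):
        mesh = build_annulus_mesh(6.0, 10.0, 4, 40)
        assert validate_mesh(mesh) == []
        passive_faces = np.flatnonzero(mesh.passive)
        assert len(passive_faces) == 40
        for f in passive_faces:
            assert all(mesh.role[v] == A7_BORDER for v in mesh.faces[f])
        inner_r = np.linalg.norm(mesh.positions[mesh.role == INNER_BORDER], axis=1)
        assert np.allclose(inner_r, 6.0)

    def test_rejects_inverted_radii(self):
        with pytest.raises(ValueError):
            build_annulus_mesh(10.0, 6.0, 4, 40)


class TestAreaPerimeter:
    def test_unit_square(self, unit_square_mesh):
        assert cell_area(unit_square_mesh, 0) == pytest.approx(1.0)
        assert cell_perimeter(unit_square_mesh, 0) == pytest.approx(4.0)

    def test_regular_hexagon_closed_forms(self):
        mesh = build_hexagonal_sheet(1, 1, 1.0)
        assert cell_area(mesh, 0) == pytest.approx(3 * np.sqrt(3) / 2, rel=1e-9)
        assert cell_perimeter(mesh, 0) == pytest.approx(6.0, rel=1e-9)

    def test_convex_pentagon_matches_fan_triangulation(self):
        rng = np.random.default_rng(3)
        # convex pentagon: sorted angles on a noisy circle
        ang = np.sort(rng.uniform(0, 2 * np.pi, 5))
        radii = rng.uniform(1.0, 2.0)
        pts = np.column_stack([radii * np.cos(ang), radii * np.sin(ang)])
        mesh = TissueMesh(pts, np.array([[i, (i + 1) % 5] for i in range(5)]),
                          [[0, 1, 2, 3, 4]])
        fan = 0.0
        for i in range(1, 4):
            a, b, c = pts[0], pts[i], pts[i + 1]
            u, v = b - a, c - a
            fan += 0.5 * abs(u[0] * v[1] - u[1] * v[0])
        assert cell_area(mesh, 0) == pytest.approx(fan, rel=1e-12)

    @settings(max_examples=30, deadline=None)
    @given(
        angle=st.floats(-np.pi, np.pi),
        tx=st.floats(-5, 5),
        ty=st.floats(-5, 5),
    )
    def test_rigid_motion_invariance(self, angle, tx, ty):
        mesh = build_hexagonal_sheet(2, 2, 0.9)
        a0 = [cell_area(mesh, f) for f in range(mesh.n_faces)]
        p0 = [cell_perimeter(mesh, f) for f in range(mesh.n_faces)]
        R = np.array([[np.cos(angle), -np.sin(angle)], [np.sin(angle), np.cos(angle)]])
        mesh.positions = mesh.positions @ R.T + np.array([tx, ty])
        mesh.invalidate()
        for f in range(mesh.n_faces):
            assert cell_area(mesh, f) == pytest.approx(a0[f], rel=1e-12, abs=1e-12)
            assert cell_perimeter(mesh, f) == pytest.approx(p0[f], rel=1e-12, abs=1e-12)

    def test_degenerate_face_raises(self, unit_square_mesh):
        with pytest.raises(Exception):
            cell_area(unit_square_mesh, [0, 1])


class TestEdgeAngle:
    def test_parallel_and_perpendicular(self, down_frame):
        assert edge_angle((0, 0), (0, 1), down_frame) == pytest.approx(0.0)
        assert edge_angle((0, 0), (1, 0), down_frame) == pytest.approx(90.0)

    def test_radial_frame_perpendicular_edge(self):
        # AP direction at the midpoint of an edge from (10,0) to (10,1)
        # points from outside toward the origin; the vertical edge is
        # perpendicular to it up to the tiny tilt of the midpoint.
        frame = APFrame(mode="radial", centre=(0.0, 0.0))
        theta = edge_angle((10.0, 0.0), (10.0, 1.0), frame)
        assert abs(theta) == pytest.approx(90.0, abs=3.0)

    def test_45_degree_sign_convention(self, down_frame):
        # An edge along +45 deg from the x-axis tilts clockwise from the
        # downward AP axis: right oblique, positive theta.
        assert edge_angle((0, 0), (1, 1), down_frame) == pytest.approx(45.0)
        assert edge_angle((0, 0), (-1, 1), down_frame) == pytest.approx(-45.0)

    DOWN = APFrame(mode="cartesian", ap_vector=(0.0, -1.0))

    @settings(max_examples=50, deadline=None)
    @given(
        x1=st.floats(-3, 3), y1=st.floats(-3, 3),
        x2=st.floats(-3, 3), y2=st.floats(-3, 3),
    )
    def test_swap_invariance_and_interval(self, x1, y1, x2, y2):
        if abs(x1 - x2) < 1e-6 and abs(y1 - y2) < 1e-6:
            return
        t1 = edge_angle((x1, y1), (x2, y2), self.DOWN)
        t2 = edge_angle((x2, y2), (x1, y1), self.DOWN)
        assert t1 == pytest.approx(t2, abs=1e-9)
        assert -90.0 < t1 <= 90.0

    @settings(max_examples=50, deadline=None)
    @given(
        x1=st.floats(-3, 3), y1=st.floats(-3, 3),
        x2=st.floats(-3, 3), y2=st.floats(-3, 3),
    )
    def test_mirror_negates_angle(self, x1, y1, x2, y2):
        if abs(x1 - x2) < 1e-6 and abs(y1 - y2) < 1e-6:
            return
        t = edge_angle((x1, y1), (x2, y2), self.DOWN)
        tm = edge_angle((-x1, y1), (-x2, y2), self.DOWN)
        if abs(t) > 89.9:  # the fold point maps to itself
            return
        assert tm == pytest.approx(-t, abs=1e-9)

    def test_zero_length_edge_raises(self, down_frame):
        with pytest.raises(Exception):
            edge_angle((1, 1), (1, 1), down_frame)

    def test_fold_convention(self):
        assert fold_angle_deg(90.0) == 90.0
        assert fold_angle_deg(-90.0) == 90.0
        assert fold_angle_deg(135.0) == -45.0
        assert fold_angle_deg(180.0) == pytest.approx(0.0)


class TestValidateMesh:
    def test_fresh_sheet_is_clean(self):
        assert validate_mesh(build_hexagonal_sheet(3, 3, 1.0)) == []

    def test_reversed_loop_reports_winding(self):
        mesh = build_hexagonal_sheet(2, 2, 1.0)
        mesh.faces[0] = list(reversed(mesh.faces[0]))
        mesh.invalidate()
        assert any("wound clockwise" in msg for msg in validate_mesh(mesh))

    def test_missing_junction_reported(self):
        mesh = build_hexagonal_sheet(2, 2, 1.0)
        mesh.junctions = mesh.junctions[:-1]
        mesh.invalidate()
        assert any("missing from junction table" in m for m in validate_mesh(mesh))


class TestSnapshotIO:
    def test_roundtrip(self, tmp_path):
        mesh = build_annulus_mesh(6.0, 10.0, 3, 12)
        path = tmp_path / "mesh.json"
        save_mesh(mesh, path)
        back = load_mesh(path)
        assert np.allclose(back.positions, mesh.positions)
        assert np.array_equal(back.junctions, mesh.junctions)
        assert back.faces == mesh.faces
        assert np.array_equal(back.passive, mesh.passive)
        assert np.array_equal(back.role, mesh.role)
        assert back.expected_euler == mesh.expected_euler
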