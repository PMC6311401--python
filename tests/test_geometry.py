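"""Geometry primitives: line fitting, angles, cross sections, sampling."""

import numpy as np
import pytest
import trimesh
from hypothesis import given, settings
from hypothesis import strategies as st

from rootaxis.geometry import (
    DegeneracyWarning,
    GeometryError,
    Line3D,
    OutlineLoop,
    Plane,
    TriangleMesh,
    angle_between_lines,
    best_fit_line,
    equidistant_landmarks,
    plane_mesh_intersection,
    surface_sample_uniform,
)

from conftest import icosphere


# ---------------------------------------------------------------------------
# best_fit_line
# ---------------------------------------------------------------------------


class TestBestFitLine:
    def test_collinear_points_recover_exact_direction(self):
        line = best_fit_line([[0, 0, 0], [1, 1, 1], [2, 2, 2]])
        assert np.allclose(line.anchor, [1, 1, 1])
        assert np.allclose(line.direction, np.ones(3) / np.sqrt(3))

    def test_cylinder_sample_aligns_with_axis(self):
        # symmetric grid on a cylinder: the TLS direction is exactly z
        theta = 2 * np.pi * np.arange(5) / 5
        z = np.linspace(-6, 6, 10)
        pts = np.array([[2 * np.cos(t), 2 * np.sin(t), zi] for zi in z for t in theta])
        line = best_fit_line(pts)
        assert abs(abs(line.direction[2]) - 1.0) < 1e-6

    def test_single_point_rejected(self):
        with pytest.raises(GeometryError):
            best_fit_line([[1.0, 2.0, 3.0]])
        with pytest.raises(GeometryError):
            best_fit_line([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])

    def test_matches_independent_svd_oracle(self):
        # independent route: eigen-decomposition of the scatter matrix
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = rng.integers(3, 40)
            pts = rng.normal(size=(n, 3)) * np.array([5.0, 1.0, 0.5])
            c = pts - pts.mean(axis=0)
            evals, evecs = np.linalg.eigh(c.T @ c)
            oracle = evecs[:, np.argmax(evals)]
            line = best_fit_line(pts)
            assert abs(float(line.direction @ oracle)) > 1 - 1e-9

    def test_isotropic_cloud_warns_and_is_deterministic(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(500, 3))
        sym = np.vstack([pts, -pts, pts[:, [1, 2, 0]], -pts[:, [1, 2, 0]],
                         pts[:, [2, 0, 1]], -pts[:, [2, 0, 1]]])
        with pytest.warns(DegeneracyWarning):
            a = best_fit_line(sym)
        with pytest.warns(DegeneracyWarning):
            b = best_fit_line(sym)
        assert np.allclose(a.direction, b.direction)


# ---------------------------------------------------------------------------
# angle_between_lines
# ---------------------------------------------------------------------------


class TestAngleBetweenLines:
    def test_known_angles(self):
        x = Line3D([0, 0, 0], [1, 0, 0])
        y = Line3D([5, 5, 5], [0, 1, 0])
        assert angle_between_lines(x, x) == 0.0
        assert angle_between_lines(x, y) == pytest.approx(90.0)
        t = np.radians(10)
        tilted = Line3D([0, 0, 0], [0, np.sin(t), np.cos(t)])
        z = Line3D([0, 0, 0], [0, 0, 1])
        assert angle_between_lines(z, tilted) == pytest.approx(10.0, abs=1e-9)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=50, deadline=None)
    def test_symmetric_flip_invariant_and_bounded(self, seed):
        rng = np.random.default_rng(seed)
        a = Line3D(rng.normal(size=3), rng.normal(size=3) + 1e-3)
        b = Line3D(rng.normal(size=3), rng.normal(size=3) + 1e-3)
        ang = angle_between_lines(a, b)
        assert 0.0 <= ang <= 90.0
        assert ang == pytest.approx(angle_between_lines(b, a))
        flipped = Line3D(a.anchor, -a.direction)
        assert ang == pytest.approx(angle_between_lines(flipped, b))


# ---------------------------------------------------------------------------
# plane_mesh_intersection
# ---------------------------------------------------------------------------


class TestPlaneMeshIntersection:
    def test_sphere_equator_perimeter(self, unit_sphere):
        loops = plane_mesh_intersection(unit_sphere, Plane([0, 0, 0], [0, 0, 1]))
        assert len(loops) == 1
        assert loops[0].perimeter() == pytest.approx(2 * np.pi, rel=0.02)

    def test_matches_trimesh_section_length(self, unit_sphere):
        loops = plane_mesh_intersection(unit_sphere, Plane([0, 0, 0.3], [0, 0, 1]))
        section = unit_sphere.to_trimesh().section(
            plane_origin=[0, 0, 0.3], plane_normal=[0, 0, 1]
        )
        total = sum(lp.perimeter() for lp in loops)
        assert total == pytest.approx(section.length, rel=1e-6)

    def test_plane_outside_bounding_box(self, unit_sphere):
        assert plane_mesh_intersection(unit_sphere, Plane([0, 0, 5], [0, 0, 1])) == []

    def test_torus_axial_plane_gives_two_loops(self):
        tor = TriangleMesh.from_trimesh(
            trimesh.creation.torus(major_radius=3.0, minor_radius=1.0)
        )
        loops = plane_mesh_intersection(tor, Plane([0, 0, 0], [1, 0, 0]))
        assert len(loops) == 2
        for lp in loops:
            assert lp.perimeter() == pytest.approx(2 * np.pi, rel=0.05)

    def test_perimeter_error_decreases_with_resolution(self):
        errors = []
        for sub in (2, 3, 4):
            mesh = icosphere(1.0, sub)
            loops = plane_mesh_intersection(mesh, Plane([0, 0, 0], [0, 0, 1]))
            errors.append(abs(loops[0].perimeter() - 2 * np.pi))
        assert errors[0] > errors[1] > errors[2]

    def test_loops_sorted_by_area_and_lie_on_plane(self):
        tor = TriangleMesh.from_trimesh(
            trimesh.creation.torus(major_radius=4.0, minor_radius=1.5)
        )
        plane = Plane([0, 0, 0], [0, 0, 1])  # equatorial: two concentric loops
        loops = plane_mesh_intersection(tor, plane)
        assert len(loops) == 2
        assert loops[0].enclosed_area() >= loops[1].enclosed_area()
        for lp in loops:
            assert np.max(np.abs(plane.signed_distance(lp.points))) < 1e-6


# ---------------------------------------------------------------------------
# equidistant_landmarks
# ---------------------------------------------------------------------------


def _square_loop(side=4.0):
    pts = np.array(
        [[0, 0, 0], [side, 0, 0], [side, side, 0], [0, side, 0]], dtype=float
    )
    return OutlineLoop(pts, Plane([0, 0, 0], [0, 0, 1]))


class TestEquidistantLandmarks:
    def test_square_corners(self):
        lm = equidistant_landmarks(_square_loop(4.0), 4)
        assert len(lm) == 4
        closed = np.vstack([lm, lm[:1]])
        spacing = np.linalg.norm(np.diff(closed, axis=0), axis=1)
        assert np.allclose(spacing, 4.0)
        assert np.allclose(lm[0], [0, 0, 0])  # min-x start rule

    def test_circle_equal_chords(self):
        theta = 2 * np.pi * np.arange(720) / 720
        pts = np.column_stack([np.cos(theta), np.sin(theta), np.zeros_like(theta)])
        loop = OutlineLoop(pts, Plane([0, 0, 0], [0, 0, 1]))
        lm = equidistant_landmarks(loop, 5)
        closed = np.vstack([lm, lm[:1]])
        chords = np.linalg.norm(np.diff(closed, axis=0), axis=1)
        assert np.allclose(chords, 2 * np.sin(np.pi / 5), atol=1e-4)
        assert np.ptp(chords) < 1e-6

    def test_too_few_landmarks_rejected(self):
        with pytest.raises(GeometryError):
            equidistant_landmarks(_square_loop(), 2)


# ---------------------------------------------------------------------------
# surface_sample_uniform
# ---------------------------------------------------------------------------


class TestSurfaceSampleUniform:
    def test_area_proportional_face_counts(self, cube_mesh):
        n = 1000
        pts = surface_sample_uniform(cube_mesh, n, seed=123)
        assert pts.shape == (n, 3)
        # classify points by the cube face they lie on; each of the 6
        # faces has probability 1/6 under area uniformity
        counts = np.zeros(6)
        for p in pts:
            axis = np.argmax(np.abs(np.abs(p) - 0.5) < 1e-9)
            counts[2 * axis + (p[axis] > 0)] += 1
        expected = n / 6
        sd = np.sqrt(n * (1 / 6) * (5 / 6))
        assert np.all(np.abs(counts - expected) < 4 * sd)

    def test_deterministic_given_seed(self, cube_mesh):
        a = surface_sample_uniform(cube_mesh, 100, seed=9)
        b = surface_sample_uniform(cube_mesh, 100, seed=9)
        assert np.array_equal(a, b)
        c = surface_sample_uniform(cube_mesh, 100, seed=10)
        assert not np.array_equal(a, c)

    def test_exclusion_predicate(self, cube_mesh):
        pts = surface_sample_uniform(
            cube_mesh, 200, seed=1, exclude=lambda c: c[:, 2] > 0.4
        )
        on_top = (
            (np.abs(pts[:, 2] - 0.5) < 1e-9)
            & (np.abs(pts[:, 0]) < 0.5 - 1e-9)
            & (np.abs(pts[:, 1]) < 0.5 - 1e-9)
        )
        assert not on_top.any()

    def test_invalid_inputs(self, cube_mesh):
        with pytest.raises(GeometryError):
            surface_sample_uniform(cube_mesh, 0, seed=1)
        with pytest.raises(GeometryError):
            surface_sample_uniform(cube_mesh, 10, seed=1, exclude=lambda c: np.ones(len(c), bool))


# ---------------------------------------------------------------------------
# TriangleMesh invariants
# ---------------------------------------------------------------------------


class TestTriangleMeshValidation:
    def test_bad_face_index(self):
        with pytest.raises(GeometryError):
            TriangleMesh([[0, 0, 0], [1, 0, 0], [0, 1, 0]], [[0, 1, 3]]).validate()

    def test_repeated_vertex_in_face(self):
        with pytest.raises(GeometryError):
            TriangleMesh([[0, 0, 0], [1, 0, 0], [0, 1, 0]], [[0, 1, 1]]).validate()

    def test_zero_area_face(self):
        with pytest.raises(GeometryError):
            TriangleMesh(
                [[0, 0, 0], [1, 0, 0], [2, 0, 0]], [[0, 1, 2]]
            ).validate()

    def test_watertightness_flags(self, unit_sphere):
        assert unit_sphere.is_watertight()
        open_mesh = TriangleMesh(unit_sphere.vertices, unit_sphere.faces[:-1])
        assert not open_mesh.is_watertight()
        assert open_mesh.boundary_edge_count() == 3
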