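"""Geometric correctness of the shape measures."""

import numpy as np
import pytest
import trimesh

from subshape.shape import (
    InvalidMeshError,
    MedialCurve,
    fit_medial_curve,
    log_jacobian,
    radial_distance,
    triangle_areas,
    vertex_areas,
)

from conftest import capped_cylinder


class TestMedialCurve:
    def test_cylinder_medial_lies_on_axis(self):
        verts, faces = capped_cylinder(radius=5.0, length=30.0)
        medial = fit_medial_curve(verts, faces)
        # axial cross-section centroids sit on the z-axis (within 1% of r)
        assert np.abs(medial.points[:, :2]).max() < 0.05 * 5.0

    def test_sphere_collapses_to_centroid(self):
        sphere = trimesh.creation.icosphere(3, radius=4.0)
        sphere.apply_translation([1.0, -2.0, 3.0])
        medial = fit_medial_curve(np.asarray(sphere.vertices), np.asarray(sphere.faces))
        assert len(medial) == 1
        np.testing.assert_allclose(medial.points[0], [1.0, -2.0, 3.0], atol=1e-6)

    def test_arc_tube_medial_follows_arc(self):
        # 90-degree circular-arc tube: analytic arc of cross-section
        # centroids is the oracle
        arc_r, tube_r, n = 20.0, 2.0, 48
        psi = np.linspace(0, np.pi / 2, n)
        phi = np.linspace(0, 2 * np.pi, 16, endpoint=False)
        centers = np.stack([arc_r * np.cos(psi), arc_r * np.sin(psi), np.zeros(n)], 1)
        normal = np.stack([np.cos(psi), np.sin(psi), np.zeros(n)], 1)
        binorm = np.array([0.0, 0.0, 1.0])
        taper = np.sqrt(np.maximum(1 - np.linspace(-1, 1, n) ** 8, 0))
        rings = (
            centers[:, None, :]
            + (tube_r * taper)[:, None, None] * np.cos(phi)[None, :, None] * normal[:, None, :]
            + (tube_r * taper)[:, None, None] * np.sin(phi)[None, :, None] * binorm[None, None, :]
        )
        verts = np.concatenate([centers[:1], rings.reshape(-1, 3), centers[-1:]])
        cols = len(phi)
        faces = []
        top, bottom = 0, n * cols + 1

        def rid(i, j):
            return 1 + i * cols + (j % cols)

        for j in range(cols):
            faces.append([top, rid(0, j + 1), rid(0, j)])
        for i in range(n - 1):
            for j in range(cols):
                faces.append([rid(i, j), rid(i, j + 1), rid(i + 1, j + 1)])
                faces.append([rid(i, j), rid(i + 1, j + 1), rid(i + 1, j)])
        for j in range(cols):
            faces.append([bottom, rid(n - 1, j), rid(n - 1, j + 1)])
        medial = fit_medial_curve(verts, np.asarray(faces), n_samples=12, validate=False)
        # every fitted medial point lies close to the analytic arc
        d_to_arc = np.abs(np.hypot(medial.points[:, 0], medial.points[:, 1]) - arc_r)
        assert np.max(d_to_arc) < 0.25 * tube_r
        assert np.abs(medial.points[:, 2]).max() < 0.25 * tube_r

    def test_open_mesh_rejected(self):
        verts, faces = capped_cylinder()
        with pytest.raises(InvalidMeshError):
            fit_medial_curve(verts, faces[:-5])


class TestRadialDistance:
    def test_cylinder_thickness_equals_radius(self):
        verts, faces = capped_cylinder(radius=5.0, length=30.0, rows=40)
        medial = MedialCurve(np.array([[0, 0, -15.0], [0, 0, 15.0]]))
        th = radial_distance(verts, medial)
        lateral = np.abs(verts[:, 2]) < 8.0
        np.testing.assert_allclose(th[lateral], 5.0, rtol=0.01)

    def test_sphere_thickness_is_radius_exactly(self):
        sphere = trimesh.creation.icosphere(2, radius=3.0)
        th = radial_distance(np.asarray(sphere.vertices), MedialCurve(np.zeros((1, 3))))
        np.testing.assert_allclose(th, 3.0, atol=1e-9)

    def test_point_segment_distance(self):
        medial = MedialCurve(np.array([[0, 0, -1.0], [0, 0, 1.0]]))
        th = radial_distance(np.array([[3.0, 4.0, 0.0]]), medial)
        assert th[0] == pytest.approx(5.0, abs=1e-12)

    def test_projection_onto_segment_interior_not_samples(self):
        # nearest point is inside a segment, closer than either endpoint
        medial = MedialCurve(np.array([[-10.0, 0, 0], [10.0, 0, 0]]))
        th = radial_distance(np.array([[3.7, 2.0, 0.0]]), medial)
        assert th[0] == pytest.approx(2.0, abs=1e-12)

    def test_empty_medial_rejected(self):
        with pytest.raises(ValueError):
            radial_distance(np.zeros((3, 3)), None)


class TestVertexAreas:
    def test_single_triangle_splits_equally(self):
        verts = np.array([[0, 0, 0], [1.0, 0, 0], [0, 1.0, 0]])
        areas = vertex_areas(verts, np.array([[0, 1, 2]]))
        np.testing.assert_allclose(areas, 0.5 / 3.0)

    def test_total_area_conserved(self, atlas):
        mesh = atlas.get("putamen", "L")
        np.testing.assert_allclose(
            vertex_areas(mesh.vertices, mesh.faces).sum(),
            triangle_areas(mesh.vertices, mesh.faces).sum(),
            rtol=1e-12,
        )

    def test_icosahedron_symmetry(self):
        ico = trimesh.creation.icosahedron()
        areas = vertex_areas(np.asarray(ico.vertices), np.asarray(ico.faces))
        np.testing.assert_allclose(areas, areas[0], rtol=1e-9)

    def test_degenerate_triangle_warns(self):
        verts = np.array([[0, 0, 0], [1.0, 0, 0], [2.0, 0, 0], [0, 1.0, 0]])
        with pytest.warns(RuntimeWarning):
            areas = vertex_areas(verts, np.array([[0, 1, 2], [0, 1, 3]]))
        assert areas[2] == 0.0


class TestLogJacobian:
    def test_identity_is_zero(self, atlas):
        mesh = atlas.get("caudate", "R")
        lj = log_jacobian(mesh.vertices, mesh.vertices, mesh.faces)
        np.testing.assert_allclose(lj, 0.0, atol=1e-14)

    def test_uniform_scale(self, atlas):
        mesh = atlas.get("amygdala", "L")
        lj = log_jacobian(mesh.vertices * 1.1, mesh.vertices, mesh.faces)
        np.testing.assert_allclose(lj, 2 * np.log(1.1), atol=1e-12)

    def test_matches_bruteforce_area_ratio(self, atlas):
        mesh = atlas.get("hippocampus", "R")
        rng = np.random.default_rng(7)
        # smooth random deformation
        warped = mesh.vertices * (1 + 0.05 * np.sin(mesh.vertices / 4.0))
        warped += rng.normal(0, 0.01, mesh.vertices.shape)
        lj = log_jacobian(warped, mesh.vertices, mesh.faces)
        brute = np.log(
            vertex_areas(warped, mesh.faces) / vertex_areas(mesh.vertices, mesh.faces)
        )
        np.testing.assert_allclose(lj, brute, atol=1e-12)

    def test_area_conservation_identity(self, atlas):
        # sum_v tmplArea(v) * exp(logJ(v)) = total subject area, exactly
        mesh = atlas.get("thalamus", "L")
        warped = mesh.vertices * 1.07
        lj = log_jacobian(warped, mesh.vertices, mesh.faces)
        lhs = (vertex_areas(mesh.vertices, mesh.faces) * np.exp(lj)).sum()
        rhs = triangle_areas(warped, mesh.faces).sum()
        np.testing.assert_allclose(lhs, rhs, rtol=1e-12)

    def test_topology_mismatch_rejected(self, atlas):
        mesh = atlas.get("caudate", "R")
        with pytest.raises(ValueError):
            log_jacobian(mesh.vertices[:-1], mesh.vertices, mesh.faces)


class TestInvariances:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_rigid_motion_invariance(self, atlas, seed):
        from scipy.spatial.transform import Rotation

        mesh = atlas.get("pallidum", "R")
        rng = np.random.default_rng(seed)
        R = Rotation.random(rng=rng).as_matrix()
        t = rng.normal(0, 10, 3)
        subj = mesh.vertices * 1.03
        lj0 = log_jacobian(subj, mesh.vertices, mesh.faces)
        lj1 = log_jacobian(subj @ R.T + t, mesh.vertices @ R.T + t, mesh.faces)
        np.testing.assert_allclose(lj0, lj1, atol=1e-9)
        medial = fit_medial_curve(mesh.vertices, mesh.faces, validate=False)
        medial_moved = MedialCurve(medial.points @ R.T + t)
        th0 = radial_distance(mesh.vertices, medial)
        th1 = radial_distance(mesh.vertices @ R.T + t, medial_moved)
        np.testing.assert_allclose(th0, th1, atol=1e-9)

    def test_radial_inflation_increases_thickness(self, atlas):
        mesh = atlas.get("putamen", "R")
        medial = mesh.medial_curve
        _, proj = medial.nearest(mesh.vertices)
        inflated = proj + (mesh.vertices - proj) * 1.2
        assert np.all(
            radial_distance(inflated, medial) > radial_distance(mesh.vertices, medial) - 1e-12
        )
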