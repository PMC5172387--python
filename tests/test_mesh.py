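"""Geometry: medial curves, radial distance, log-Jacobian, volume."""

import numpy as np
import pytest
import trimesh

import shapeherit as sh
from shapeherit.mesh import vertex_one_ring_areas

from conftest import make_bent_tube, make_cylinder


def random_rigid(rng):
    A = rng.normal(size=(3, 3))
    Q, _ = np.linalg.qr(A)
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    t = rng.normal(scale=10.0, size=3)
    return Q, t


class TestMedialCurve:
    def test_cylinder_curve_lies_on_axis(self):
        mesh, _ = make_cylinder()
        curve = sh.fit_medial_curve(mesh, n_points=15)
        assert np.abs(curve.points[:, :2]).max() < 1e-6

    def test_bent_tube_follows_centerline(self):
        mesh, centerline = make_bent_tube(radius=1.0)
        curve = sh.fit_medial_curve(mesh, n_points=25)
        devs = [np.linalg.norm(centerline - p, axis=1).min() for p in curve.points]
        assert max(devs) < 0.05  # within 5% of the tube radius

    def test_spherical_mesh_rejected_by_eigenvalue_ratio(self):
        ico = trimesh.creation.icosphere(subdivisions=2, radius=5.0)
        mesh = sh.SurfaceMesh(np.asarray(ico.vertices), np.asarray(ico.faces))
        with pytest.raises(ValueError, match="eigenvalue-ratio"):
            sh.fit_medial_curve(mesh)

    def test_arc_length_monotone(self):
        mesh, _ = make_bent_tube()
        curve = sh.fit_medial_curve(mesh, n_points=20)
        assert np.all(np.diff(curve.arc_length) > 0)


class TestRadialDistance:
    def test_cylinder_distances_equal_radius(self):
        mesh, n_lateral = make_cylinder(radius=2.0)
        curve = sh.fit_medial_curve(mesh, n_points=15)
        d = sh.radial_distance(mesh, curve)[:n_lateral]
        # interior rings: distance = radius up to discretization near the ends
        inner = d[(np.abs(mesh.vertices[:n_lateral, 2]) < 7.0)]
        assert np.allclose(inner, 2.0, atol=1e-8)

    def test_distances_nonnegative_everywhere(self):
        mesh, _ = make_bent_tube()
        curve = sh.fit_medial_curve(mesh)
        assert (sh.radial_distance(mesh, curve) >= 0).all()


class TestLogJacobian:
    def test_identity_is_zero(self):
        template = sh.make_template(100)
        assert np.allclose(sh.log_jacobian(template, template), 0.0)

    def test_uniform_scale_gives_2_log_s(self):
        template = sh.make_template(150)
        for s in (0.5, 1.3, 2.0):
            subject = sh.SurfaceMesh(template.vertices * s, template.faces)
            lj = sh.log_jacobian(subject, template)
            assert np.allclose(lj, 2.0 * np.log(s), atol=1e-10)

    def test_local_one_ring_doubling_gives_log_2(self):
        # flat hexagonal fan: scaling the ring by sqrt(2) doubles every
        # incident triangle area, so the center vertex reads ln 2
        ang = np.linspace(0, 2 * np.pi, 6, endpoint=False)
        ring = np.column_stack([np.cos(ang), np.sin(ang), np.zeros(6)])
        verts = np.vstack([[0.0, 0.0, 0.0], ring])
        faces = np.array([[0, 1 + i, 1 + (i + 1) % 6] for i in range(6)])
        template = sh.SurfaceMesh(verts, faces)
        scaled = np.vstack([[0.0, 0.0, 0.0], np.sqrt(2.0) * ring])
        subject = sh.SurfaceMesh(scaled, faces)
        lj = sh.log_jacobian(subject, template)
        assert abs(lj[0] - np.log(2.0)) < 1e-12

    def test_topology_mismatch_rejected(self):
        a = sh.make_template(100)
        b = sh.make_template(200)
        with pytest.raises(ValueError, match="topology"):
            sh.log_jacobian(a, b)

    def test_cohort_mean_scales_with_log_inflation(self):
        template = sh.make_template(120)
        rng = np.random.default_rng(3)
        cohort = [sh.SurfaceMesh(template.vertices * (1 + 0.01 * rng.normal()),
                                 template.faces) for _ in range(10)]
        base = np.mean([sh.log_jacobian(m, template) for m in cohort], axis=0)
        s = 1.25
        inflated = np.mean([sh.log_jacobian(
            sh.SurfaceMesh(m.vertices * s, m.faces), template) for m in cohort], axis=0)
        assert np.allclose(inflated - base, 2.0 * np.log(s), atol=1e-10)


class TestVolume:
    def test_unit_cube_volume_exactly_one(self):
        box = trimesh.creation.box(extents=(1.0, 1.0, 1.0))
        mesh = sh.SurfaceMesh(np.asarray(box.vertices), np.asarray(box.faces))
        assert sh.gross_volume(mesh) == pytest.approx(1.0, abs=1e-12)

    def test_icosphere_volume_within_half_percent(self):
        ico = trimesh.creation.icosphere(subdivisions=4, radius=10.0)
        mesh = sh.SurfaceMesh(np.asarray(ico.vertices), np.asarray(ico.faces))
        expected = 4.0 / 3.0 * np.pi * 10.0 ** 3
        assert abs(sh.gross_volume(mesh) - expected) / expected < 0.005
        # matches the independent trimesh computation
        assert sh.gross_volume(mesh) == pytest.approx(float(ico.volume), rel=1e-10)

    def test_cm3_conversion(self):
        box = trimesh.creation.box(extents=(10.0, 10.0, 10.0))
        mesh = sh.SurfaceMesh(np.asarray(box.vertices), np.asarray(box.faces))
        assert sh.gross_volume(mesh, to_cm3=True) == pytest.approx(1.0)

    def test_inward_orientation_corrected(self):
        box = trimesh.creation.box(extents=(2.0, 2.0, 2.0))
        flipped = sh.SurfaceMesh(np.asarray(box.vertices),
                                 np.asarray(box.faces)[:, [0, 2, 1]])
        assert sh.gross_volume(flipped) == pytest.approx(8.0)

    def test_open_mesh_rejected(self):
        verts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0]], float)
        tri = sh.SurfaceMesh(verts, np.array([[0, 1, 2]]))
        with pytest.raises(ValueError, match="closed"):
            sh.gross_volume(tri)


class TestInvariances:
    def test_rigid_motion_invariance(self, rng):
        template = sh.make_template(200)
        subj = sh.SurfaceMesh(
            template.vertices + 0.2 * rng.normal(size=template.vertices.shape),
            template.faces)
        curve = sh.fit_medial_curve(template)
        rd0 = sh.radial_distance(subj, curve)
        lj0 = sh.log_jacobian(subj, template)
        Q, t = random_rigid(rng)
        t_rot = sh.SurfaceMesh(template.vertices @ Q.T + t, template.faces)
        s_rot = sh.SurfaceMesh(subj.vertices @ Q.T + t, subj.faces)
        curve_rot = sh.fit_medial_curve(t_rot)
        assert np.allclose(sh.radial_distance(s_rot, curve_rot), rd0, atol=1e-8)
        assert np.allclose(sh.log_jacobian(s_rot, t_rot), lj0, atol=1e-8)

    def test_measures_bitwise_reproducible(self):
        template = sh.make_template(100)
        rng = np.random.default_rng(0)
        subj = sh.SurfaceMesh(template.vertices + 0.1 * rng.normal(size=template.vertices.shape),
                              template.faces)
        curve = sh.fit_medial_curve(template)
        assert np.array_equal(sh.radial_distance(subj, curve), sh.radial_distance(subj, curve))
        assert np.array_equal(sh.log_jacobian(subj, template), sh.log_jacobian(subj, template))

    def test_one_ring_areas_sum_to_surface_area(self):
        template = sh.make_template(150)
        total = vertex_one_ring_areas(template).sum()
        assert total == pytest.approx(float(template.to_trimesh().area), rel=1e-10)


def test_ply_round_trip(tmp_path):
    template = sh.make_template(100)
    path = tmp_path / "mesh.ply"
    template.save_ply(path, vertex_scalar=np.linspace(0, 1, template.n_vertices))
    loaded = sh.SurfaceMesh.load_ply(path)
    assert np.allclose(loaded.vertices, template.vertices, atol=1e-6)
    assert np.array_equal(loaded.faces, template.faces)


def test_measure_matrix_tsv_round_trip(tmp_path):
    rng = np.random.default_rng(1)
    mm = sh.ShapeMeasureMatrix(np.abs(rng.normal(size=(5, 8))) + 1.0)
    path = tmp_path / "m.tsv"
    mm.to_tsv(path)
    back = sh.ShapeMeasureMatrix.from_tsv(path)
    assert np.allclose(back.values, mm.values)
    assert np.array_equal(back.subject_ids, mm.subject_ids)
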