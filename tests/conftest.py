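import numpy as np
import pytest

import shapeherit as sh


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_config():
    return sh.SimulationConfig(n_subjects=200, n_variants=400, n_vertices=60, seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    """Genotypes, QC'd matrix and GRM shared by read-only tests."""
    geno = sh.generate_genotypes(small_config)
    qc = sh.filter_variants(geno)
    grm = sh.compute_grm(qc)
    return {"geno": geno, "qc": qc, "grm": grm, "config": small_config}


def make_cylinder(radius=2.0, length=20.0, n_rings=21, n_seg=24):
    """Closed cylinder along z with cap fans; lateral vertices first."""
    zs = np.linspace(-length / 2, length / 2, n_rings)
    ang = np.linspace(0, 2 * np.pi, n_seg, endpoint=False)
    verts = [[radius * np.cos(a), radius * np.sin(a), z] for z in zs for a in ang]
    top = len(verts)
    verts.append([0.0, 0.0, length / 2])
    bottom = len(verts)
    verts.append([0.0, 0.0, -length / 2])

    def vid(i, j):
        return i * n_seg + (j % n_seg)

    faces = []
    for i in range(n_rings - 1):
        for j in range(n_seg):
            a, b = vid(i, j), vid(i, j + 1)
            c, d = vid(i + 1, j), vid(i + 1, j + 1)
            faces.append([a, b, c])
            faces.append([b, d, c])
    for j in range(n_seg):
        faces.append([top, vid(n_rings - 1, j), vid(n_rings - 1, j + 1)])
        faces.append([bottom, vid(0, j + 1), vid(0, j)])
    mesh = sh.SurfaceMesh(np.asarray(verts), np.asarray(faces), structure="cylinder")
    v, f = mesh.vertices, mesh.faces
    signed = np.einsum("ij,ij->i", v[f[:, 0]], np.cross(v[f[:, 1]], v[f[:, 2]])).sum()
    if signed < 0:
        mesh.faces = mesh.faces[:, [0, 2, 1]]
    return mesh, n_rings * n_seg  # mesh, number of lateral vertices


def make_bent_tube(radius=1.0, length=40.0, sag=3.0, n_rings=41, n_seg=20):
    """Tube around the planar centerline x = sag * (1 - (2z/L)^2)."""
    ts = np.linspace(-length / 2, length / 2, n_rings)
    ang = np.linspace(0, 2 * np.pi, n_seg, endpoint=False)
    verts = []
    for t in ts:
        cx = sag * (1.0 - (2.0 * t / length) ** 2)
        # tangent of the centerline
        tan = np.array([-8.0 * sag * t / length ** 2, 0.0, 1.0])
        tan /= np.linalg.norm(tan)
        n1 = np.cross(tan, [0.0, 1.0, 0.0])
        n1 /= np.linalg.norm(n1)
        n2 = np.cross(tan, n1)
        c = np.array([cx, 0.0, t])
        for a in ang:
            verts.append(c + radius * (np.cos(a) * n1 + np.sin(a) * n2))
    top = len(verts)
    verts.append([sag * (1 - 1.0), 0.0, length / 2])
    bottom = len(verts)
    verts.append([sag * (1 - 1.0), 0.0, -length / 2])

    def vid(i, j):
        return i * n_seg + (j % n_seg)

    faces = []
    for i in range(n_rings - 1):
        for j in range(n_seg):
            a, b = vid(i, j), vid(i, j + 1)
            c, d = vid(i + 1, j), vid(i + 1, j + 1)
            faces.append([a, b, c])
            faces.append([b, d, c])
    for j in range(n_seg):
        faces.append([top, vid(n_rings - 1, j), vid(n_rings - 1, j + 1)])
        faces.append([bottom, vid(0, j + 1), vid(0, j)])
    centerline = np.array([[sag * (1.0 - (2.0 * t / length) ** 2), 0.0, t]
                           for t in np.linspace(-length / 2, length / 2, 4001)])
    return sh.SurfaceMesh(np.asarray(verts), np.asarray(faces), structure="tube"), centerline
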