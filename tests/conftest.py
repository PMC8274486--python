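import numpy as np
import pytest
import scipy.spatial
import trimesh

from laaecap.mesh import SurfaceMesh
from laaecap.synthetic import ShapeSpec, make_dataset


@pytest.fixture(scope="session")
def icosphere():
    ico = trimesh.creation.icosphere(subdivisions=3, radius=1.0)
    return SurfaceMesh(np.array(ico.vertices), np.array(ico.faces)).validate()


@pytest.fixture(scope="session")
def icosphere2():
    ico = trimesh.creation.icosphere(subdivisions=3, radius=2.0)
    return SurfaceMesh(np.array(ico.vertices), np.array(ico.faces)).validate()


@pytest.fixture(scope="session")
def unit_square():
    """Two right triangles forming the unit square in z=0, CCW from +z."""
    v = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], dtype=float)
    f = np.array([[0, 1, 2], [0, 2, 3]])
    return SurfaceMesh(v, f).validate()


@pytest.fixture(scope="session")
def planar_grid():
    """Regular triangulated grid in z=0, faces CCW from +z."""
    n = 9
    xs, ys = np.meshgrid(np.linspace(0, 1, n), np.linspace(0, 1, n), indexing="ij")
    v = np.column_stack([xs.ravel(), ys.ravel(), np.zeros(n * n)])
    faces = []
    for i in range(n - 1):
        for j in range(n - 1):
            a = i * n + j
            b = a + 1
            c = a + n
            d = c + 1
            faces.append([a, d, b])
            faces.append([a, c, d])
    return SurfaceMesh(v, np.array(faces)).validate()


@pytest.fixture(scope="session")
def disc_mesh():
    """Structured planar disc of radius 1 (~720 vertices)."""
    nr, nt = 18, 40
    pts = [[0.0, 0.0]]
    for i in range(1, nr + 1):
        r = i / nr
        for j in range(nt):
            a = 2 * np.pi * j / nt
            pts.append([r * np.cos(a), r * np.sin(a)])
    pts = np.array(pts)
    tri = scipy.spatial.Delaunay(pts)
    faces = tri.simplices.copy()
    v = np.column_stack([pts, np.zeros(len(pts))])
    cr = np.cross(v[faces[:, 1]] - v[faces[:, 0]], v[faces[:, 2]] - v[faces[:, 0]])
    faces[cr[:, 2] < 0] = faces[cr[:, 2] < 0][:, ::-1]
    return SurfaceMesh(v, faces).validate()


@pytest.fixture(scope="session")
def tube_spec():
    """Straight, unlobed, unit-size tube (cylinder-like with an apex cap)."""
    return ShapeSpec(
        n_axial=30,
        n_circ=40,
        bend_amplitude=0.0,
        radius_variation=0.0,
        lobe_count_range=(0, 0),
        lobe_amp_range=(0.0, 1e-9),
        scale_range=(1.0, 1.0),
        base_radius=1.0,
        base_length=1.0,
        min_radius=0.01,
    )


@pytest.fixture(scope="session")
def laa_dataset():
    """200 synthetic LAA cases with oracle targets (shared across tests)."""
    return make_dataset(200, seed=11)


@pytest.fixture(scope="session")
def small_laa():
    spec = ShapeSpec(n_axial=24, n_circ=16)
    from laaecap.synthetic import sample_shape

    return sample_shape(spec, seed=5)
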