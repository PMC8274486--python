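import numpy as np
import pytest

from laaecap.flatten import (
    angular_parameterize,
    apex_vertex,
    build_flat_map,
    extract_isolines,
    geodesic_distance,
    sample_field,
    to_bullseye,
    unflatten,
)
from laaecap.mesh import SurfaceMesh
from laaecap.synthetic import sample_shape


@pytest.fixture(scope="module")
def tube(tube_spec):
    return sample_shape(tube_spec, seed=1)


@pytest.fixture(scope="module")
def laa_with_dist(small_laa):
    return small_laa, geodesic_distance(small_laa, small_laa.ostium_ring)


class TestGeodesics:
    def test_zero_on_source(self, disc_mesh):
        d = geodesic_distance(disc_mesh, [0])
        assert d[0] == 0.0 and d.min() >= 0

    def test_planar_disc_accuracy(self, disc_mesh):
        d = geodesic_distance(disc_mesh, [0])
        r = np.linalg.norm(disc_mesh.vertices[:, :2], axis=1)
        sel = r > 0.1
        assert (np.abs(d[sel] - r[sel]) / r[sel]).max() < 0.02

    def test_icosphere_great_circle(self, icosphere):
        src = int(np.argmax(icosphere.vertices[:, 2]))
        d = geodesic_distance(icosphere, [src])
        anti = int(np.argmin(icosphere.vertices[:, 2]))
        assert abs(d[anti] - np.pi) < 0.05 * np.pi
        equator = np.flatnonzero(np.abs(icosphere.vertices[:, 2]) < 0.05)
        assert np.abs(d[equator] - np.pi / 2).max() < 0.05 * (np.pi / 2)

    def test_unreachable_vertices_error(self):
        v = np.array(
            [[0, 0, 0], [1, 0, 0], [0, 1, 0], [5, 5, 0], [6, 5, 0], [5, 6, 0]],
            dtype=float,
        )
        m = SurfaceMesh(v, [[0, 1, 2], [3, 4, 5]])  # not validated on purpose
        with pytest.raises(ValueError, match="unreachable"):
            geodesic_distance(m, [0])


class TestApex:
    def test_tube_apex_is_cap(self, tube):
        d = geodesic_distance(tube, tube.ostium_ring)
        assert apex_vertex(d) == tube.n_vertices - 1

    def test_tie_breaks_to_lowest_index(self):
        assert apex_vertex(np.array([1.0, 3.0, 3.0, 2.0])) == 1

    def test_sphere_antipode(self, icosphere):
        src = int(np.argmax(icosphere.vertices[:, 2]))
        d = geodesic_distance(icosphere, [src])
        apex = apex_vertex(d)
        assert icosphere.vertices[apex, 2] < -0.95


class TestIsolines:
    def test_cylinder_circumference(self, tube):
        h = tube.vertices[:, 2].copy()
        for iso in extract_isolines(tube, h, 4):
            r = np.cos(0.5 * np.pi * iso.level) ** 0.8  # tube radius profile
            assert abs(iso.length() - 2 * np.pi * r) / (2 * np.pi * r) < 0.01

    def test_points_sit_on_level(self, tube):
        h = tube.vertices[:, 2].copy()
        for iso in extract_isolines(tube, h, 3):
            assert np.abs(iso.points[:, 2] - iso.level).max() < 1e-9

    def test_epsilon_inset_levels(self, tube):
        h = tube.vertices[:, 2].copy()
        isos = extract_isolines(tube, h, 2)
        hmax = h.max()
        assert np.isclose(isos[0].level, 0.25 * hmax)
        assert np.isclose(isos[1].level, 0.75 * hmax)

    def test_no_crossing_errors(self, tube):
        with pytest.raises(ValueError):
            extract_isolines(tube, np.zeros(tube.n_vertices), 2)


class TestAngular:
    def test_planar_circle_reference(self):
        th = np.linspace(0, 2 * np.pi, 64, endpoint=False)
        circ = np.c_[np.cos(th), np.sin(th), np.zeros(64)]
        ang = angular_parameterize(circ, np.array([1.0, 0, 0]), np.array([0, 0, 1.0]))
        assert ang[0] == 0.0
        assert np.isclose(ang[16], np.pi / 2)

    def test_strictly_increasing_coverage(self):
        th = np.linspace(0, 2 * np.pi, 50, endpoint=False)
        circ = np.c_[2 * np.cos(th), 2 * np.sin(th), np.full(50, 3.0)]
        ang = angular_parameterize(circ, circ[0], np.array([0, 0, 1.0]))
        assert np.all(np.diff(ang) > 0)
        assert ang.min() >= 0 and ang.max() < 2 * np.pi

    def test_rigid_invariance(self):
        from scipy.spatial.transform import Rotation

        th = np.linspace(0, 2 * np.pi, 40, endpoint=False)
        circ = np.c_[np.cos(th), np.sin(th), np.zeros(40)]
        R = Rotation.from_euler("xyz", [0.4, 0.9, -0.2]).as_matrix()
        ang0 = angular_parameterize(circ, circ[5], np.array([0, 0, 1.0]))
        ang1 = angular_parameterize(circ @ R.T + 7.0, circ[5] @ R.T + 7.0, R @ [0, 0, 1.0])
        assert np.abs(ang0 - ang1).max() < 1e-9

    def test_centroid_coincident_point_errors(self):
        pts = np.zeros((5, 3))
        with pytest.raises(ValueError):
            angular_parameterize(pts, np.array([1.0, 0, 0]), np.array([0, 0, 1.0]))


class TestFlatMap:
    def test_grid_shape_and_bary(self, laa_with_dist):
        mesh, d = laa_with_dist
        flat = build_flat_map(mesh, d, mesh.landmark, R=16, A=24)
        assert flat.channels.shape == (16, 24, 3)
        assert np.abs(flat.corr_bary.sum(axis=2) - 1.0).max() < 1e-12
        assert np.all(flat.corr_bary >= 0)

    def test_cylinder_rows_are_circles(self, tube):
        h = tube.vertices[:, 2].copy()
        flat = build_flat_map(tube, h, tube.landmark, R=8, A=32)
        for r in range(8):
            ring = flat.channels[r]
            c = ring.mean(axis=0)
            radius = np.cos(0.5 * np.pi * flat.d_levels[r] * flat.d_max) ** 0.8
            err = np.abs(np.linalg.norm(ring[:, :2] - c[:2], axis=1) - radius)
            assert err.max() / radius < 0.01

    def test_rigid_invariance_of_correspondence(self, laa_with_dist):
        from scipy.spatial.transform import Rotation

        mesh, d = laa_with_dist
        flat0 = build_flat_map(mesh, d, mesh.landmark, R=8, A=16)
        R = Rotation.from_euler("zxy", [1.0, 0.2, -0.5]).as_matrix()
        moved = SurfaceMesh(
            mesh.vertices @ R.T + [4.0, -1.0, 2.0],
            mesh.faces,
            fields=dict(mesh.fields),
            ostium_ring=mesh.ostium_ring,
            landmark=mesh.landmark,
        )
        flat1 = build_flat_map(moved, d, moved.landmark, R=8, A=16)
        assert np.array_equal(flat0.corr_faces, flat1.corr_faces)
        assert np.abs(flat0.corr_bary - flat1.corr_bary).max() < 1e-6
        back = (flat1.channels - [4.0, -1.0, 2.0]) @ R
        assert np.abs(back - flat0.channels).max() < 1e-6


class TestBullseye:
    def test_padding_and_mask_area(self, laa_with_dist):
        mesh, d = laa_with_dist
        flat = build_flat_map(mesh, d, mesh.landmark, R=8, A=16)
        grid = sample_field(d, mesh, flat)
        be = to_bullseye(flat, 128, grid, pad_value=-7.0)
        assert np.all(be.image[~be.mask] == -7.0)
        assert abs(be.mask.mean() - np.pi / 4) / (np.pi / 4) < 0.02

    def test_constant_grid_constant_image(self, laa_with_dist):
        mesh, d = laa_with_dist
        flat = build_flat_map(mesh, d, mesh.landmark, R=8, A=16)
        be = to_bullseye(flat, 64, np.full((8, 16), 3.25))
        assert np.allclose(be.image[be.mask], 3.25)

    def test_mask_rotation_symmetric(self, laa_with_dist):
        mesh, d = laa_with_dist
        flat = build_flat_map(mesh, d, mesh.landmark, R=8, A=16)
        be = to_bullseye(flat, 64, np.zeros((8, 16)))
        assert np.array_equal(be.mask, np.rot90(be.mask))


class TestUnflatten:
    def test_constant_grid(self, laa_with_dist):
        mesh, d = laa_with_dist
        flat = build_flat_map(mesh, d, mesh.landmark, R=8, A=16)
        out = unflatten(mesh, flat, np.full((8, 16), 2.5))
        assert np.allclose(out, 2.5)

    def test_geodesic_roundtrip(self, laa_with_dist):
        mesh, d = laa_with_dist
        flat = build_flat_map(mesh, d, mesh.landmark, R=128, A=128)
        back = unflatten(mesh, flat, sample_field(d, mesh, flat))
        assert np.abs(back - d).mean() < 0.02 * d.max()

    def test_transport_converges_with_resolution(self, laa_with_dist):
        mesh, d = laa_with_dist
        errs = []
        for n in (32, 128):
            flat = build_flat_map(mesh, d, mesh.landmark, R=n, A=n)
            back = unflatten(mesh, flat, sample_field(d, mesh, flat))
            errs.append(np.abs(back - d).mean())
        assert errs[1] < errs[0]

    def test_linear_height_on_cylinder(self, tube):
        h = tube.vertices[:, 2].copy()
        flat = build_flat_map(tube, h, tube.landmark, R=64, A=64)
        back = unflatten(tube, flat, sample_field(h, tube, flat))
        assert np.abs(back - h).max() < 0.01 * np.ptp(h)

    def test_bullseye_and_cartesian_agree(self, laa_with_dist):
        from laaecap.adapters import bullseye_to_grid

        mesh, d = laa_with_dist
        flat = build_flat_map(mesh, d, mesh.landmark, R=32, A=32)
        grid = sample_field(d, mesh, flat)
        be = to_bullseye(flat, 256, grid)
        grid_back = bullseye_to_grid(be.image[:, :, 0], flat)
        v_cart = unflatten(mesh, flat, grid)
        v_be = unflatten(mesh, flat, grid_back)
        assert np.abs(v_cart - v_be).mean() < 0.02 * d.max()
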