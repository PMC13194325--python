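"""Geometric substrate: I/O, volume, voxelization, Boolean ops, plane cuts,
sphere fitting and smoothing, checked against closed-form solids."""

import numpy as np
import pytest
import trimesh

from femurpdm import mesh as M


def _tetrahedron():
    verts = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])
    faces = np.array([[0, 2, 1], [0, 1, 3], [0, 3, 2], [1, 2, 3]])
    return M.as_mesh(verts, faces)


class TestIO:
    def test_stl_roundtrip_welds_duplicates(self, tmp_path):
        tet = _tetrahedron()
        path = tmp_path / "tet.stl"
        M.write_mesh(tet, path)
        back = M.read_mesh(path)
        assert len(back.vertices) == 4
        assert len(back.faces) == 4
        # STL stores float32: agreement to single precision
        a = np.sort(np.asarray(back.vertices), axis=0)
        b = np.sort(np.asarray(tet.vertices), axis=0)
        assert np.abs(a - b).max() < 1e-6

    def test_binary_stl_size_is_format_arithmetic(self, tmp_path, icosphere):
        path = tmp_path / "s.stl"
        M.write_mesh(icosphere, path)
        assert path.stat().st_size == 84 + 50 * len(icosphere.faces)

    def test_ascii_stl_roundtrip(self, tmp_path):
        tet = _tetrahedron()
        path = tmp_path / "tet_ascii.stl"
        M.write_mesh(tet, path, "stl_ascii")
        back = M.read_mesh(path, "stl")
        assert len(back.faces) == 4

    def test_ply_roundtrip_is_exact(self, tmp_path):
        tet = _tetrahedron()
        tet.vertices += np.pi * 1e-7  # irrational offsets stress precision
        path = tmp_path / "tet.ply"
        M.write_mesh(tet, path)
        back = M.read_mesh(path)
        a = np.asarray(back.vertices)
        b = np.asarray(tet.vertices)
        # welding may reorder vertices; compare as sorted row sets
        order_a = np.lexsort(a.T)
        order_b = np.lexsort(b.T)
        assert np.abs(a[order_a] - b[order_b]).max() == 0.0

    def test_ply_scalar_attribute_survives_roundtrip(self, tmp_path):
        tet = _tetrahedron()
        scalar = np.array([0.5, -1.25, 3.0, 0.0])
        path = tmp_path / "dev.ply"
        M.write_ply_with_scalar(tet, scalar, path)
        assert np.array_equal(M.read_ply_scalar(path), scalar)
        assert len(M.read_mesh(path).faces) == 4

    def test_malformed_and_empty_files_raise(self, tmp_path):
        bad = tmp_path / "bad.stl"
        bad.write_bytes(b"not a mesh at all")
        with pytest.raises(M.MeshError):
            M.read_mesh(bad)
        with pytest.raises(M.MeshError):
            M.read_mesh(tmp_path / "nope.xyz")


class TestVolume:
    def test_cube_closed_form(self, unit_cube):
        assert M.mesh_volume(unit_cube) == pytest.approx(1.0, abs=1e-12)

    def test_icosphere_matches_analytic(self, icosphere):
        analytic = 4.0 / 3.0 * np.pi  # r = 10 mm -> cm^3
        assert M.mesh_volume(icosphere) == pytest.approx(analytic, rel=5e-3)

    def test_inverted_orientation_raises(self, unit_cube):
        inv = M.as_mesh(unit_cube.vertices, unit_cube.faces[:, ::-1])
        with pytest.raises(M.MeshError, match="inverted"):
            M.mesh_volume(inv)

    def test_open_mesh_raises_naming_boundary_edges(self, unit_cube):
        open_mesh = M.as_mesh(unit_cube.vertices, unit_cube.faces[:-2])
        with pytest.raises(M.MeshError, match="boundary edges"):
            M.mesh_volume(open_mesh)


class TestVoxelize:
    def test_cube_volume_within_two_percent(self, unit_cube):
        grid = M.voxelize(unit_cube, 0.5)
        assert grid.volume == pytest.approx(1.0, rel=0.02)

    def test_halving_pitch_does_not_worsen_volume(self, unit_cube):
        errs = [abs(M.voxelize(unit_cube, p).volume - 1.0)
                for p in (2.0, 1.0, 0.5)]
        assert errs[1] <= errs[0] + 1e-12
        assert errs[2] <= errs[1] + 1e-12

    def test_pitch_larger_than_mesh_raises(self, unit_cube):
        with pytest.raises(M.MeshError):
            M.voxelize(unit_cube, 50.0)

    def test_open_mesh_rejected(self, unit_cube):
        open_mesh = M.as_mesh(unit_cube.vertices, unit_cube.faces[:-1])
        with pytest.raises(M.MeshError):
            M.voxelize(open_mesh, 0.5)


@pytest.fixture(scope="module")
def cylinder_grids():
    outer = trimesh.creation.cylinder(radius=15.0, height=100.0, sections=128)
    inner = trimesh.creation.cylinder(radius=6.0, height=100.0, sections=128)
    bounds = np.array(outer.bounds)
    bounds[0] -= 1.0
    bounds[1] += 1.0
    go = M.voxelize(M.as_mesh(outer.vertices, outer.faces), 0.5, bounds)
    gi = M.voxelize(M.as_mesh(inner.vertices, inner.faces), 0.5, bounds)
    return go, gi


class TestBooleanSubtract:
    def test_hollow_cylinder_canal_volume(self, cylinder_grids):
        go, gi = cylinder_grids
        shell = M.OccupancyGrid(go.origin, go.pitch,
                                go.occupancy & ~gi.occupancy)
        canal = M.boolean_subtract(go, shell)
        assert M.is_closed(canal)
        assert M.mesh_volume(canal) == pytest.approx(np.pi * 0.6 ** 2 * 10.0,
                                                     rel=0.05)

    def test_no_cavity_is_signalled_explicitly(self, cylinder_grids):
        go, _ = cylinder_grids
        assert M.boolean_subtract(go, go) is None

    def test_subtracting_empty_preserves_volume(self, cylinder_grids):
        go, _ = cylinder_grids
        empty = M.OccupancyGrid(go.origin, go.pitch,
                                np.zeros_like(go.occupancy))
        full = M.boolean_subtract(go, empty)
        assert M.mesh_volume(full) == pytest.approx(np.pi * 1.5 ** 2 * 10.0,
                                                    rel=0.02)

    def test_grid_mismatch_raises(self, cylinder_grids):
        go, gi = cylinder_grids
        other = M.OccupancyGrid(go.origin + 1.0, go.pitch, go.occupancy)
        with pytest.raises(M.MeshError):
            M.boolean_subtract(go, other)

    def test_hdf5_roundtrip(self, cylinder_grids, tmp_path):
        import h5py
        go, _ = cylinder_grids
        with h5py.File(tmp_path / "g.h5", "w") as fh:
            go.to_hdf5(fh.create_group("grid"))
        with h5py.File(tmp_path / "g.h5") as fh:
            back = M.OccupancyGrid.from_hdf5(fh["grid"])
        assert back.same_lattice(go)
        assert np.array_equal(back.occupancy, go.occupancy)


class TestCutWithPlane:
    def test_cube_midplane_capped(self, unit_cube):
        plane = M.OsteotomyPlane(point=[0, 0, 0], normal=[0, 0, -1])
        half = M.cut_with_plane(unit_cube, plane, cap=True)
        assert M.is_closed(half)
        assert M.mesh_volume(half) == pytest.approx(0.5, abs=1e-9)

    def test_cap_boundary_lies_on_plane(self, unit_cube):
        plane = M.OsteotomyPlane(point=[0, 0, 1.234], normal=[0, 0, -1])
        half = M.cut_with_plane(unit_cube, plane, cap=True)
        d = plane.signed_distance(half.vertices)
        near = np.abs(d) < 0.5
        on_plane = np.abs(d[near])
        assert on_plane.max() < 1e-6

    def test_oblique_cylinder_cut_gives_analytic_ellipse(self):
        cyl = trimesh.creation.cylinder(radius=5.0, height=60.0, sections=256)
        cyl = M.as_mesh(cyl.vertices, cyl.faces)
        n = np.array([0.0, 1.0, 1.0]) / np.sqrt(2.0)
        plane = M.OsteotomyPlane(point=[0, 0, 0], normal=-n)
        cut = M.cut_with_plane(cyl, plane, cap=True)
        assert M.is_closed(cut)
        # boundary ring of the cap: on-plane vertices shared with the wall
        d = np.abs(plane.signed_distance(cut.vertices))
        ring = cut.vertices[d < 1e-6]
        radial = np.linalg.norm(np.asarray(ring)
                                - np.asarray(ring).mean(axis=0), axis=1)
        # exclude the fan centroid vertex (radius ~0)
        radial = radial[radial > 1.0]
        assert radial.max() == pytest.approx(5.0 * np.sqrt(2.0), rel=0.02)
        assert radial.min() == pytest.approx(5.0, rel=0.02)

    def test_plane_missing_mesh_warns_and_returns_input(self, unit_cube):
        plane = M.OsteotomyPlane(point=[0, 0, -100.0], normal=[0, 0, 1])
        with pytest.warns(UserWarning):
            out = M.cut_with_plane(unit_cube, plane)
        assert out is unit_cube


class TestFitSphere:
    def test_exact_points_recovered(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(50, 3))
        pts = 23.0 * pts / np.linalg.norm(pts, axis=1, keepdims=True)
        center, radius, rms = M.fit_sphere(pts + [5.0, -2.0, 11.0])
        assert np.abs(center - [5.0, -2.0, 11.0]).max() < 1e-6
        assert radius == pytest.approx(23.0, abs=1e-6)
        assert rms < 1e-9

    def test_four_points_match_circumsphere_closed_form(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(4, 3)) * 10.0
        # independent oracle: exact circumsphere from the linear system of
        # equal squared distances
        A = 2.0 * (pts[1:] - pts[0])
        rhs = (pts[1:] ** 2).sum(axis=1) - (pts[0] ** 2).sum()
        center_o = np.linalg.solve(A, rhs)
        radius_o = np.linalg.norm(pts[0] - center_o)
        center, radius, rms = M.fit_sphere(pts)
        assert np.abs(center - center_o).max() < 1e-8
        assert radius == pytest.approx(radius_o, abs=1e-8)

    def test_hemisphere_with_noise_is_nearly_unbiased(self):
        radii = []
        for seed in range(30):
            rng = np.random.default_rng(seed)
            pts = rng.normal(size=(400, 3))
            pts /= np.linalg.norm(pts, axis=1, keepdims=True)
            pts = pts[pts[:, 2] > 0] * 23.0  # upper hemisphere
            pts += rng.normal(0.0, 0.1, size=pts.shape)
            radii.append(M.fit_sphere(pts)[1])
        assert abs(np.mean(radii) - 23.0) < 0.05

    def test_coplanar_points_raise(self):
        pts = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0],
                        [0.3, 0.7, 0]])
        with pytest.raises(M.MeshError):
            M.fit_sphere(pts)


class TestSmooth:
    def test_zero_iterations_is_identity(self, icosphere):
        out = M.smooth(icosphere, iterations=0)
        assert np.array_equal(np.asarray(out.vertices),
                              np.asarray(icosphere.vertices))

    def test_noisy_sphere_residual_decreases(self, icosphere):
        rng = np.random.default_rng(1)
        noisy = M.as_mesh(
            np.asarray(icosphere.vertices)
            + rng.normal(0, 0.2, size=(len(icosphere.vertices), 1))
            * np.asarray(icosphere.vertex_normals),
            icosphere.faces)

        def rms_radial(m):
            r = np.linalg.norm(m.vertices, axis=1)
            return np.sqrt(np.mean((r - r.mean()) ** 2))

        out = M.smooth(noisy, iterations=10)
        assert rms_radial(out) < rms_radial(noisy)
        assert len(out.vertices) == len(noisy.vertices)

    def test_volume_drift_under_one_percent(self, icosphere):
        out = M.smooth(icosphere, iterations=10)
        assert M.mesh_volume(out) == pytest.approx(
            M.mesh_volume(icosphere), rel=0.01)
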