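"""Morphometric features measured against generator ground truth and
constructed solids."""

import numpy as np
import pytest
import trimesh

from femurpdm import mesh as M
from femurpdm import morphometrics as mm
from femurpdm.anatomy import AnatomicalFrame
from femurpdm.synthetic import FemurParams, generate_femur


def ringed_cylinder(radius=14.0, height=120.0, ring_step=2.0, sections=64):
    """Closed cylinder with wall vertex rings every ``ring_step`` mm, so
    transverse vertex slabs are populated at every height."""
    n_rings = int(height / ring_step) + 1
    theta = np.linspace(0.0, 2 * np.pi, sections, endpoint=False)
    ring = np.column_stack([radius * np.cos(theta), radius * np.sin(theta)])
    verts = [np.column_stack([ring, np.full(sections, k * ring_step)])
             for k in range(n_rings)]
    verts = np.vstack(verts)
    faces = []
    for k in range(n_rings - 1):
        a = k * sections + np.arange(sections)
        b = (a + 1) % sections + k * sections
        c, d = a + sections, (a + 1) % sections + (k + 1) * sections
        faces.extend(np.column_stack([a, b, d]))
        faces.extend(np.column_stack([a, d, c]))
    bot = len(verts)
    top = bot + 1
    verts = np.vstack([verts, [0.0, 0.0, 0.0],
                       [0.0, 0.0, (n_rings - 1) * ring_step]])
    for i in range(sections):
        faces.append([bot, (i + 1) % sections, i])
        base = (n_rings - 1) * sections
        faces.append([top, base + i, base + (i + 1) % sections])
    return M.as_mesh(verts, np.array(faces))


def rotated_cylinder(angle_deg, radius=14.0, height=120.0):
    cyl = ringed_cylinder(radius=radius, height=height)
    a = np.radians(angle_deg)
    R = np.array([[np.cos(a), 0, np.sin(a)], [0, 1, 0],
                  [-np.sin(a), 0, np.cos(a)]])
    return M.as_mesh(np.asarray(cyl.vertices) @ R.T, cyl.faces)


def _cylinder_with_axial_head():
    cyl = ringed_cylinder(radius=12.0, height=120.0)
    sph = trimesh.creation.icosphere(subdivisions=3, radius=20.0)
    sverts = np.asarray(sph.vertices) + [0, 0, 135.0]
    combo = trimesh.util.concatenate(
        trimesh.Trimesh(np.asarray(cyl.vertices), cyl.faces),
        trimesh.Trimesh(sverts, sph.faces))
    return M.as_mesh(combo.vertices, combo.faces)


class TestShaftAxis:
    def test_vertical_cylinder(self):
        est = mm.shaft_axis(rotated_cylinder(0.0))
        angle = np.degrees(np.arccos(min(est.direction[2], 1.0)))
        assert angle < 0.1
        assert est.rms_residual < 0.1

    def test_coronal_tilt_recovered(self):
        est = mm.shaft_axis(rotated_cylinder(7.0))
        angle = np.degrees(np.arctan2(est.direction[0], est.direction[2]))
        assert angle == pytest.approx(7.0, abs=0.3)

    def test_short_mesh_raises(self):
        est_mesh = ringed_cylinder(height=40.0)
        with pytest.raises(mm.MeasurementError, match="60"):
            mm.shaft_axis(est_mesh)


class TestNeckAxisAndVersion:
    def test_head_center_recovered_within_half_millimetre(self,
                                                          default_femur):
        _, outer, _, truth = default_femur
        center, _ = mm.neck_axis(outer, truth.landmarks["head_seed"])
        assert np.linalg.norm(center - truth.head_center) < 0.5

    @pytest.mark.parametrize("version", [15.0, -13.0])
    def test_version_recovery(self, version):
        p = FemurParams(mesh_resolution=1.5, version=version)
        outer, _, truth = generate_femur(p, 2, compute_truth_volume=False)
        v = mm.femoral_version(outer, truth.landmarks["head_seed"])
        assert v == pytest.approx(version, abs=1.0)

    def test_zero_version_neck_in_coronal_plane(self):
        p = FemurParams(mesh_resolution=1.5, version=0.0)
        outer, _, truth = generate_femur(p, 2, compute_truth_volume=False)
        v = mm.femoral_version(outer, truth.landmarks["head_seed"])
        assert abs(v) < 1.0

    def test_canal_mesh_has_no_head(self, default_femur):
        _, _, canal, truth = default_femur
        with pytest.raises(mm.MeasurementError, match="head"):
            mm.neck_axis(canal, truth.landmarks["head_seed"])


class TestVarusValgusAndNSA:
    @pytest.mark.parametrize("vv", [0.0, 7.0, -2.0])
    def test_varus_valgus_recovery(self, vv):
        p = FemurParams(mesh_resolution=1.5, varus_valgus=vv)
        outer, _, _ = generate_femur(p, 3, compute_truth_volume=False)
        assert mm.varus_valgus(outer) == pytest.approx(vv, abs=0.5)

    def test_nsa_recovery_at_table_mean(self):
        p = FemurParams(mesh_resolution=1.5, neck_shaft_angle=125.0)
        outer, _, truth = generate_femur(p, 4, compute_truth_volume=False)
        nsa = mm.neck_shaft_angle(outer, truth.landmarks["head_seed"])
        assert nsa == pytest.approx(125.0, abs=1.5)

    def test_nsa_invariant_to_version(self):
        vals = []
        for v in (0.0, 30.0):
            p = FemurParams(mesh_resolution=1.5, version=v)
            outer, _, truth = generate_femur(p, 5,
                                             compute_truth_volume=False)
            vals.append(mm.neck_shaft_angle(outer,
                                            truth.landmarks["head_seed"]))
        assert vals[0] == pytest.approx(vals[1], abs=0.5)

    def test_collinear_neck_degenerate(self):
        """A 'head' sphere sitting on the shaft axis has no defined neck
        direction; the degenerate geometry is flagged."""
        combo = _cylinder_with_axial_head()
        with pytest.raises(mm.MeasurementError):
            mm.neck_shaft_angle(combo, np.array([0.0, 0.0, 135.0]))


class TestOffsets:
    def test_hfo_matches_construction_closed_form(self, default_femur):
        params, outer, _, truth = default_femur
        vfo, hfo = mm.offsets(outer, truth.landmarks["head_seed"],
                              truth.landmarks["lt_apex"])
        analytic = params.neck_length * np.sin(
            np.radians(180.0 - params.neck_shaft_angle)) / 10.0
        assert hfo == pytest.approx(analytic, abs=0.2)

    def test_missing_lt_apex_flags_vfo(self, default_femur):
        _, outer, _, truth = default_femur
        vfo, hfo = mm.offsets(outer, truth.landmarks["head_seed"], None)
        assert vfo is None and hfo > 0

    def test_raising_mesh_raises_vfo_exactly(self, default_femur):
        _, outer, _, truth = default_femur
        lt = truth.landmarks["lt_apex"]
        seed = truth.landmarks["head_seed"]
        vfo0, _ = mm.offsets(outer, seed, lt)
        lifted = M.as_mesh(np.asarray(outer.vertices) + [0, 0, 10.0],
                           outer.faces)
        vfo1, _ = mm.offsets(lifted, seed + [0, 0, 10.0], lt)
        assert vfo1 - vfo0 == pytest.approx(1.0, abs=1e-3)

    def test_head_on_shaft_axis_gives_zero_hfo(self):
        combo = _cylinder_with_axial_head()
        _, hfo = mm.offsets(combo, np.array([0.0, 0.0, 135.0]), None)
        assert hfo < 0.05


class TestNeckCutVersion:
    @pytest.mark.parametrize("version,tol", [(0.0, 1.0), (10.0, 1.5),
                                             (25.0, 1.5)])
    def test_perpendicular_cut_recovers_version(self, version, tol):
        p = FemurParams(mesh_resolution=1.5, version=version)
        outer, _, truth = generate_femur(p, 6, compute_truth_volume=False)
        cut = M.cut_with_plane(outer, truth.osteotomy_plane, cap=True)
        v = mm.neck_cut_version(cut, truth.osteotomy_plane)
        assert v == pytest.approx(version, abs=tol)

    def test_uncapped_cut_has_no_planar_face(self):
        p = FemurParams(mesh_resolution=1.5, version=10.0)
        outer, _, truth = generate_femur(p, 6, compute_truth_volume=False)
        cut = M.cut_with_plane(outer, truth.osteotomy_plane, cap=False)
        with pytest.raises(mm.MeasurementError, match="cut face"):
            mm.neck_cut_version(cut, truth.osteotomy_plane)

    def test_chord_method_requires_elongated_face(self):
        """On a near-circular perpendicular cut face the medial-lateral
        chord does not track the neck azimuth; the face-normal surrogate
        does (the documented reason it is the default)."""
        p = FemurParams(mesh_resolution=1.5, version=10.0)
        outer, _, truth = generate_femur(p, 6, compute_truth_volume=False)
        cut = M.cut_with_plane(outer, truth.osteotomy_plane, cap=True)
        chord = mm.neck_cut_version(cut, truth.osteotomy_plane,
                                    method="chord")
        normal = mm.neck_cut_version(cut, truth.osteotomy_plane)
        assert abs(normal - 10.0) < 1.5
        assert abs(chord - 10.0) > abs(normal - 10.0)


class TestProfileDispatch:
    def test_native_profile_recovers_everything(self, default_femur):
        params, outer, _, truth = default_femur
        prof = mm.profile(outer, truth.landmarks, "native")
        t = truth.profile
        assert prof.nfv_or_pfv == pytest.approx(t.nfv_or_pfv, abs=1.0)
        assert prof.varus_valgus == pytest.approx(t.varus_valgus, abs=0.5)
        assert prof.neck_shaft_angle == pytest.approx(t.neck_shaft_angle,
                                                      abs=1.5)
        assert prof.head_radius == pytest.approx(t.head_radius, rel=0.02)
        assert prof.size == pytest.approx(t.size, rel=0.03)
        assert prof.vfo == pytest.approx(t.vfo, abs=0.1)
        assert prof.hfo == pytest.approx(t.hfo, abs=0.2)
        assert prof.neck_cut_version is None

    def test_canal_profile_flags_head_features(self, default_femur):
        _, outer, canal, truth = default_femur
        cut_canal = M.cut_with_plane(canal, truth.osteotomy_plane, cap=True)
        prof = mm.profile(cut_canal, truth.landmarks, "canal",
                          cut_plane=truth.osteotomy_plane)
        assert prof.head_radius is None
        assert prof.nfv_or_pfv is None
        assert prof.size > 0

    def test_cube_as_native_fails_head_fit(self, unit_cube):
        from femurpdm.anatomy import LandmarkSet
        big = M.as_mesh(np.asarray(unit_cube.vertices) * 10.0,
                        unit_cube.faces)
        lms = LandmarkSet(points={"head_seed": [0.0, 0.0, 45.0],
                                  "lt_apex": [0.0, 0.0, 0.0]})
        with pytest.raises(mm.MeasurementError, match="head"):
            mm.profile(big, lms, "native")

    def test_unknown_model_kind_raises(self, unit_cube):
        with pytest.raises(ValueError):
            mm.profile(unit_cube, None, "femur")

    def test_frame_invariance(self, default_femur):
        """Rigidly moving mesh + landmarks together changes no feature."""
        _, outer, _, truth = default_femur
        ref = mm.profile(outer, truth.landmarks, "native")
        rng = np.random.default_rng(12)
        q = rng.normal(size=4)
        q /= np.linalg.norm(q)
        w, x, y, z = q
        R = np.array([
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z),
             2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z),
             2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x),
             1 - 2 * (x * x + y * y)]])
        t = np.array([31.0, -12.0, 55.0])
        frame = AnatomicalFrame(origin=t, x=R[:, 0], y=R[:, 1], z=R[:, 2])
        moved = M.as_mesh(np.asarray(outer.vertices) @ R.T + t, outer.faces)
        from femurpdm.anatomy import LandmarkSet
        lms = LandmarkSet({k: R @ v + t
                           for k, v in truth.landmarks.points.items()},
                          side="left")
        prof = mm.profile(moved, LandmarkSet(
            {k: frame.to_frame(v)[0] for k, v in lms.points.items()},
            side="left"), "native", frame=frame)
        for name in ("nfv_or_pfv", "varus_valgus", "neck_shaft_angle",
                     "size", "head_radius", "vfo", "hfo"):
            assert getattr(prof, name) == pytest.approx(
                getattr(ref, name), abs=1e-6)
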