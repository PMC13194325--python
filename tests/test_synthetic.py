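"""Synthetic femur generator: determinism, mesh validity, ground-truth
consistency and cohort sampling."""

import dataclasses

import numpy as np
import pytest

from femurpdm import mesh as M
from femurpdm.mesh import OsteotomyPlane
from femurpdm.synthetic import (CohortSpec, FemurParams, ParameterError,
                                StemParams, generate_femur,
                                generate_reconstructed, member_seeds,
                                sample_params)


class TestGenerateFemur:
    def test_same_seed_is_vertexwise_identical(self):
        p = FemurParams(mesh_resolution=2.0, noise_amplitude=0.3)
        a, ca, _ = generate_femur(p, 42, compute_truth_volume=False)
        b, cb, _ = generate_femur(p, 42, compute_truth_volume=False)
        assert np.array_equal(np.asarray(a.vertices), np.asarray(b.vertices))
        assert np.array_equal(np.asarray(ca.vertices), np.asarray(cb.vertices))

    def test_different_noise_seeds_differ(self):
        p = FemurParams(mesh_resolution=2.0, noise_amplitude=0.3)
        a, _, _ = generate_femur(p, 1, compute_truth_volume=False)
        b, _, _ = generate_femur(p, 2, compute_truth_volume=False)
        assert not np.array_equal(np.asarray(a.vertices),
                                  np.asarray(b.vertices))

    def test_meshes_closed_and_positively_oriented(self, default_femur):
        _, outer, canal, _ = default_femur
        for mesh in (outer, canal):
            assert M.is_closed(mesh)
            assert mesh.volume > 0

    def test_zero_version_truth_is_symmetric(self):
        p = FemurParams(version=0.0, mesh_resolution=2.0)
        _, _, truth = generate_femur(p, 0, compute_truth_volume=False)
        assert truth.profile.nfv_or_pfv == 0.0
        # the neck axis lies in the coronal plane by construction
        assert abs(truth.neck_axis_dir[1]) < 1e-12

    def test_head_radius_recovered_by_sphere_fit(self, default_femur):
        """Sphere fit to vertices near the true head center recovers the
        generating radius within 2% (voxel-pitch limited)."""
        params, outer, _, truth = default_femur
        d = np.linalg.norm(np.asarray(outer.vertices) - truth.head_center,
                           axis=1)
        pts = np.asarray(outer.vertices)[d < 1.1 * params.head_radius]
        _, radius, _ = M.fit_sphere(pts)
        assert radius == pytest.approx(params.head_radius, rel=0.02)

    def test_true_head_center_is_generating_sphere_center(self, default_femur):
        params, outer, _, truth = default_femur
        d = np.linalg.norm(np.asarray(outer.vertices) - truth.head_center,
                           axis=1)
        cap = d < 0.95 * params.head_radius + 2.0
        # vertices on the free head cap sit at exactly the head radius
        on_sphere = np.abs(d[cap] - params.head_radius)
        assert np.median(on_sphere) < 0.05

    def test_truth_volume_matches_mesh_volume(self, default_femur):
        _, outer, _, truth = default_femur
        assert M.mesh_volume(outer) == pytest.approx(truth.profile.size,
                                                     rel=0.01)

    def test_resolution_too_coarse_raises(self):
        with pytest.raises(ParameterError, match="too coarse"):
            generate_femur(FemurParams(mesh_resolution=4.0), 0)

    @pytest.mark.parametrize("bad", [
        dict(cortical_thickness=16.0),            # no canal left
        dict(neck_shaft_angle=80.0),              # outside range
        dict(version=75.0),                       # outside range
        dict(head_radius=10.0),                   # smaller than neck
        dict(global_scale=-1.0),
        dict(noise_amplitude=-0.1),
    ])
    def test_invalid_parameters_raise(self, bad):
        with pytest.raises(ParameterError):
            generate_femur(FemurParams(**bad), 0)


class TestGenerateReconstructed:
    def test_truth_version_is_stem_version(self):
        p = FemurParams(mesh_resolution=2.0, version=12.0)
        stem = StemParams(stem_version=20.0)
        mesh, truth = generate_reconstructed(p, stem, rng_seed=0,
                                             compute_truth_volume=False)
        assert truth.profile.nfv_or_pfv == 20.0
        assert M.is_closed(mesh)

    def test_stem_volume_against_voxel_oracle(self):
        """Construct volume minus bone-only volume equals the voxelized
        stem-outside-bone volume within 5%."""
        p = FemurParams(mesh_resolution=1.5, version=12.0)
        stem = StemParams(stem_version=18.0)
        outer, _, truth = generate_femur(p, 3, compute_truth_volume=False)
        construct, _ = generate_reconstructed(p, stem,
                                              cut=truth.osteotomy_plane,
                                              rng_seed=3,
                                              compute_truth_volume=False)
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            bone_only = M.cut_with_plane(outer, truth.osteotomy_plane)
        bounds = np.array(construct.bounds)
        bounds[0] -= 1.0
        bounds[1] += 1.0
        g_con = M.voxelize(construct, 0.5, bounds)
        g_bone = M.voxelize(bone_only, 0.5, bounds)
        voxel_added = M.OccupancyGrid(
            g_con.origin, g_con.pitch,
            g_con.occupancy & ~g_bone.occupancy).volume
        mesh_added = M.mesh_volume(construct) - M.mesh_volume(bone_only)
        assert mesh_added == pytest.approx(voxel_added, rel=0.05)

    def test_degenerate_stem_raises(self):
        with pytest.raises(ParameterError):
            generate_reconstructed(FemurParams(mesh_resolution=2.0),
                                   StemParams(stem_length=0.0), rng_seed=0)

    def test_plane_missing_neck_raises(self):
        plane = OsteotomyPlane(point=[0.0, 0.0, 500.0], normal=[0, 0, -1.0])
        with pytest.raises(ParameterError):
            generate_reconstructed(FemurParams(mesh_resolution=2.0),
                                   StemParams(), cut=plane, rng_seed=0)


class TestCohortSampling:
    def test_normal_version_statistics_converge(self):
        spec = CohortSpec(n=200,
                          distributions={"version": ("normal", 19.0, 9.0)},
                          rng_seed=4)
        versions = np.array([p.version for p in sample_params(spec)])
        assert abs(versions.mean() - 19.0) < 2.0
        assert abs(versions.std(ddof=1) - 9.0) < 1.5

    def test_fixed_distributions_give_identical_members(self):
        spec = CohortSpec(n=5, distributions={"version": 10.0,
                                              "head_radius": 24.0})
        members = sample_params(spec)
        assert all(m == members[0] for m in members)

    def test_seed_reproducibility_and_seed_sensitivity(self):
        dists = {"version": ("normal", 19.0, 9.0)}
        a = sample_params(CohortSpec(n=10, distributions=dists, rng_seed=1))
        b = sample_params(CohortSpec(n=10, distributions=dists, rng_seed=1))
        c = sample_params(CohortSpec(n=10, distributions=dists, rng_seed=2))
        assert a == b
        assert a != c
        assert not np.array_equal(
            member_seeds(CohortSpec(n=10, rng_seed=1)),
            member_seeds(CohortSpec(n=10, rng_seed=2)))

    def test_empty_cohort_is_not_an_error(self):
        assert sample_params(CohortSpec(n=0)) == []

    def test_invalid_distributions_raise(self):
        for dists in ({"version": ("normal", 19.0, -1.0)},
                      {"version": ("uniform", 5.0, 1.0)},
                      {"made_up_field": 1.0},
                      {"version": ("lognormal", 1.0, 1.0)}):
            with pytest.raises(ParameterError):
                CohortSpec(n=3, distributions=dists).validate()
        with pytest.raises(ParameterError):
            CohortSpec(n=-1).validate()

    def test_mixed_side_draws_both(self):
        spec = CohortSpec(n=30, side="mixed", rng_seed=0)
        sides = {p.side for p in sample_params(spec)}
        assert sides == {"left", "right"}

    def test_uniform_distribution_respects_bounds(self):
        spec = CohortSpec(n=50,
                          distributions={"version": ("uniform", -5.0, 25.0)},
                          rng_seed=9)
        versions = [p.version for p in sample_params(spec)]
        assert min(versions) >= -5.0 and max(versions) <= 25.0
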