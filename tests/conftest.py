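import numpy as np
import pytest
import trimesh

from femurpdm.mesh import as_mesh
from femurpdm.synthetic import FemurParams, generate_femur


@pytest.fixture(scope="session")
def default_femur():
    """One noise-free femur at moderate resolution, with ground truth
    (including the reference solid volume)."""
    params = FemurParams(mesh_resolution=1.5)
    outer, canal, truth = generate_femur(params, rng_seed=1)
    return params, outer, canal, truth


@pytest.fixture(scope="session")
def femur_pair_lr():
    """The same anatomy generated as a left and as a right femur."""
    left = FemurParams(mesh_resolution=1.8, side="left", version=15.0)
    right = FemurParams(mesh_resolution=1.8, side="right", version=15.0)
    outer_l, _, truth_l = generate_femur(left, 7, compute_truth_volume=False)
    outer_r, _, truth_r = generate_femur(right, 7, compute_truth_volume=False)
    return (outer_l, truth_l), (outer_r, truth_r)


@pytest.fixture
def unit_cube():
    cube = trimesh.creation.box(extents=[10.0, 10.0, 10.0])
    return as_mesh(cube.vertices, cube.faces)


@pytest.fixture
def icosphere():
    sph = trimesh.creation.icosphere(subdivisions=4, radius=10.0)
    return as_mesh(sph.vertices, sph.faces)
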