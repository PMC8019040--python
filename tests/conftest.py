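"""Shared fixtures: small meshes and point clouds reused across modules.

Session scope keeps the suite fast — fixtures are read-only for tests.
"""

import numpy as np
import pytest

import alphamorph as am


@pytest.fixture(scope="session")
def cube_mesh():
    return am.make_primitive("cube", 1.0)


@pytest.fixture(scope="session")
def sphere_mesh():
    return am.make_primitive("sphere", 1.0, resolution=3)


@pytest.fixture(scope="session")
def torus_mesh():
    return am.make_primitive("torus", 2.0)  # R=2, r=0.5


@pytest.fixture(scope="session")
def small_tube_mesh():
    spec = am.SyntheticShapeSpec(
        n_folds=3, fold_depth=0.5, fold_width=1.1, spiral_turns=1.0,
        resolution=(64, 96), seed=11,
    )
    return am.make_tube(spec)


@pytest.fixture(scope="session")
def small_tube_cloud(small_tube_mesh):
    raw = am.fill_interior(small_tube_mesh, n_min=9000, seed=1)
    cloud = am.downsample(raw, 6000, seed=2)
    am.reference_length(cloud, n_neighbors=50)
    return cloud


@pytest.fixture(scope="session")
def small_tube_curve(small_tube_cloud, small_tube_mesh):
    return am.characteristic_curve(small_tube_cloud, small_tube_mesh)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
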