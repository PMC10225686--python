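import numpy as np
import pytest

from flexmusic import (
    SourceSpace,
    build_adjacency,
    build_smoothness_dictionary,
    synthesize_source_space,
)


@pytest.fixture(scope="session")
def icosphere_forward():
    """64-channel / 162-dipole synthetic forward model (subdivided icosahedron)."""
    return synthesize_source_space(subdivisions=2, radius_mm=70.0, seed=0)


@pytest.fixture(scope="session")
def icosphere_dictionary(icosphere_forward):
    space, lead = icosphere_forward
    return build_smoothness_dictionary(lead, space, max_order=8)


@pytest.fixture()
def path_space():
    """7-node path graph with 10 mm spacing along x."""
    n = 7
    a = np.zeros((n, n), dtype=np.int8)
    for i in range(n - 1):
        a[i, i + 1] = a[i + 1, i] = 1
    pos = np.zeros((n, 3))
    pos[:, 0] = np.arange(n) * 10.0
    return SourceSpace(positions=pos, adjacency=a)


@pytest.fixture()
def triangle_pair_space():
    """4 vertices, two shared-edge triangles — tiny mesh for adjacency oracles."""
    a = build_adjacency([(0, 1, 2), (1, 2, 3)], 4)
    pos = np.array([[0, 0, 0], [10, 0, 0], [0, 10, 0], [10, 10, 0]], dtype=float)
    return SourceSpace(positions=pos, adjacency=a)
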