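import numpy as np
import pytest

from deviate.mesh import TriangleMesh
from deviate.synthetic import icosphere


@pytest.fixture(scope="session")
def tetra() -> TriangleMesh:
    """Regular tetrahedron with edge length 1 (smallest closed mesh)."""
    v = np.array(
        [[1.0, 1.0, 1.0], [1.0, -1.0, -1.0], [-1.0, 1.0, -1.0], [-1.0, -1.0, 1.0]]
    ) / (2.0 * np.sqrt(2.0))
    f = np.array([[0, 1, 2], [0, 3, 1], [0, 2, 3], [1, 3, 2]])
    return TriangleMesh(v, f)


@pytest.fixture(scope="session")
def ico2() -> TriangleMesh:
    """162-vertex icosphere (fast fixture)."""
    return icosphere(2)


@pytest.fixture(scope="session")
def ico3() -> TriangleMesh:
    """642-vertex icosphere."""
    return icosphere(3)


@pytest.fixture(scope="session")
def ico4() -> TriangleMesh:
    """2562-vertex icosphere (the simulation default)."""
    return icosphere(4)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
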