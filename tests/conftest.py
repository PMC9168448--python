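import numpy as np
import pytest

from gammasync import TriMesh, make_mesh


@pytest.fixture(scope="session")
def small_mesh() -> TriMesh:
    """120-vertex two-hemisphere test surface with all ROI labels."""
    return make_mesh(60, rng_seed=11)


@pytest.fixture(scope="session")
def grid_mesh() -> TriMesh:
    """Regular planar 41x41 triangulated grid, 1 mm spacing (one hemisphere).

    Used where an (approximately) flat regular surface makes geometric
    expectations exact (smoothing kernel width, geodesic distances).
    """
    n = 41
    xs, ys = np.meshgrid(np.arange(n, dtype=float), np.arange(n, dtype=float))
    coords = np.column_stack([xs.ravel(), ys.ravel(), np.zeros(n * n)])
    faces = []
    for i in range(n - 1):
        for j in range(n - 1):
            v = i * n + j
            faces.append([v, v + 1, v + n])
            faces.append([v + 1, v + n + 1, v + n])
    return TriMesh(coords, np.asarray(faces), np.zeros(n * n, dtype=np.int8))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
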