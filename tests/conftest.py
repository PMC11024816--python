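import numpy as np
import pytest

from tractmorph.cohort_stats import CohortMatrix
from tractmorph.mesh import HexMesh, TemplateConfig, build_template_tract_mesh


@pytest.fixture(scope="session")
def default_template() -> HexMesh:
    return build_template_tract_mesh(TemplateConfig())


@pytest.fixture(scope="session")
def small_template_config() -> TemplateConfig:
    """Reduced-resolution template used to keep simulations fast."""
    return TemplateConfig(n_u=8, n_v=8, n_w=40)


@pytest.fixture(scope="session")
def tiny_template_config() -> TemplateConfig:
    return TemplateConfig(n_u=4, n_v=4, n_w=10)


@pytest.fixture
def unit_hex() -> HexMesh:
    """A single hexahedron spanning the unit cube, VTK corner order."""
    nodes = np.array(
        [
            [0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0],
            [0, 0, 1], [1, 0, 1], [1, 1, 1], [0, 1, 1],
        ],
        dtype=float,
    )
    return HexMesh(nodes, np.arange(8)[None, :])


def make_unit_cube_grid(nx: int, ny: int, nz: int, origin=(0.0, 0.0, 0.0)) -> HexMesh:
    """Structured mesh of nx*ny*nz axis-aligned unit-cube elements."""
    from tractmorph.mesh import structured_hex_connectivity

    ax = [np.arange(n + 1, dtype=float) for n in (nx, ny, nz)]
    nodes = []
    for k in range(nz + 1):
        for j in range(ny + 1):
            for i in range(nx + 1):
                nodes.append([ax[0][i], ax[1][j], ax[2][k]])
    nodes = np.asarray(nodes) + np.asarray(origin)
    return HexMesh(nodes, structured_hex_connectivity(nx, ny, nz))


def make_cohort(X, labels=None, metric="FA", feature_indices=None) -> CohortMatrix:
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if labels is None:
        labels = ["g"] * n
    if feature_indices is None:
        feature_indices = np.arange(X.shape[1])
    return CohortMatrix(
        X, [f"s{i}" for i in range(n)], list(labels), metric, feature_indices
    )
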