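import numpy as np
import pytest

from chiralsheet.mesh import APFrame, TissueMesh, build_hexagonal_sheet


@pytest.fixture
def down_frame() -> APFrame:
    """Cartesian AP frame pointing down the page (anterior at the top)."""
    return APFrame(mode="cartesian", ap_vector=(0.0, -1.0))


@pytest.fixture
def radial_frame() -> APFrame:
    return APFrame(mode="radial", centre=(0.0, 0.0))


@pytest.fixture
def unit_square_mesh() -> TissueMesh:
    positions = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])
    junctions = np.array([[0, 1], [1, 2], [2, 3], [3, 0]])
    return TissueMesh(positions, junctions, [[0, 1, 2, 3]])


@pytest.fixture
def jittered_sheet() -> TissueMesh:
    """Small random-ish epithelial patch used by several force tests."""
    mesh = build_hexagonal_sheet(3, 3, 0.62)
    rng = np.random.default_rng(7)
    mesh.positions += rng.normal(0.0, 0.04, mesh.positions.shape)
    return mesh
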