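import numpy as np
import pytest

from morphofold import mech, synth
from morphofold.mesh import DERMIS, EPIDERMIS


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_slab():
    """Tiny bilayer slab used by the cheap solver tests."""
    spec = synth.BilayerSlabSpec(
        lateral_extent_x=0.6,
        lateral_extent_y=0.6,
        thickness_epidermis=0.1,
        thickness_dermis=0.2,
        target_edge_length=0.1,
    )
    return synth.make_bilayer_slab(spec)


@pytest.fixture(scope="session")
def soft_materials():
    m = mech.ElasticConstants(E=1.0, nu=0.2)
    return {EPIDERMIS: m, DERMIS: m}


@pytest.fixture(scope="session")
def zero_growth():
    return {EPIDERMIS: mech.GrowthLaw(), DERMIS: mech.GrowthLaw()}


@pytest.fixture
def single_tet_mesh(rng):
    """One mildly irregular, positively oriented tetrahedron."""
    from morphofold.mesh import LayeredTetMesh

    pts = np.array(
        [[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float
    ) + 0.05 * rng.standard_normal((4, 3))
    tets = np.array([[0, 1, 2, 3]])
    if np.linalg.det((pts[tets[0, 1:]] - pts[tets[0, 0]]).T) < 0:
        tets = np.array([[0, 2, 1, 3]])
    return LayeredTetMesh(
        points=pts,
        tets=tets,
        layer=np.array([DERMIS]),
        fixed_nodes=np.array([], dtype=int),
        normals=np.array([[0.0, 0.0, 1.0]]),
    )
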