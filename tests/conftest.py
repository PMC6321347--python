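import numpy as np
import pytest

from mechkit.bbfs import TSCandidate
from mechkit.geometry import Geometry
from mechkit.molgraph import build_connectivity

ELEMENTS = ["H", "C", "N", "O"]


def random_geometry(rng, n_atoms=None, box=6.0, min_sep=0.65):
    """Random gas-phase point cloud with a minimum interatomic separation."""
    n = n_atoms or rng.integers(2, 10)
    coords = []
    while len(coords) < n:
        p = rng.uniform(0.0, box, size=3)
        if all(np.linalg.norm(p - q) > min_sep for q in coords):
            coords.append(p)
    symbols = [ELEMENTS[i] for i in rng.integers(0, len(ELEMENTS), size=n)]
    return Geometry.from_symbols(symbols, np.array(coords))


def make_candidate(geom, reactant_graph=None, product_graph=None, source=""):
    """TS-candidate wrapper for screening tests."""
    cg = build_connectivity(geom)
    return TSCandidate(
        window=(0, 0),
        events=[],
        geometry=geom,
        active_atoms=set(),
        reactant_graph=reactant_graph or cg,
        product_graph=product_graph or cg,
        source=source,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20251002)


@pytest.fixture
def water():
    return Geometry.from_symbols(
        ["O", "H", "H"], [[0, 0, 0], [0.76, 0.59, 0], [-0.76, 0.59, 0]]
    )


@pytest.fixture
def formaldehyde():
    return Geometry.from_symbols(
        ["C", "O", "H", "H"],
        [[0, 0, 0], [1.21, 0, 0], [-0.55, 0.93, 0], [-0.55, -0.93, 0]],
    )
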