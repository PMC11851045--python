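import numpy as np
import pytest

from sppanel.weights import RegionSet, SpatialWeights, build_rook_from_edges
from sppanel.synthetic import lattice_weights


def moran_double_sum(x: np.ndarray, W: np.ndarray) -> float:
    """Literal double-loop Moran's I, the independent oracle."""
    n = len(x)
    z = x - x.mean()
    S0 = 0.0
    num = 0.0
    for i in range(n):
        for j in range(n):
            S0 += W[i, j]
            num += W[i, j] * z[i] * z[j]
    return n / S0 * num / np.sum(z**2)


def random_connected_weights(n: int, rng: np.random.Generator) -> SpatialWeights:
    """Random connected graph on n labelled regions (spanning tree + extras)."""
    ids = tuple(f"u{i}" for i in range(n))
    edges = []
    order = rng.permutation(n)
    for a, b in zip(order[:-1], order[1:]):  # random spanning tree
        edges.append((ids[a], ids[b]))
    n_extra = rng.integers(0, n)
    for _ in range(n_extra):
        i, j = rng.choice(n, size=2, replace=False)
        edges.append((ids[i], ids[j]))
    return build_rook_from_edges(edges, RegionSet(ids))


@pytest.fixture(scope="session")
def lattice4():
    return lattice_weights(4, 4)


@pytest.fixture(scope="session")
def lattice10():
    return lattice_weights(10, 10)


@pytest.fixture(scope="session")
def checkerboard4():
    """Alternating +/-1 attribute on the 4x4 lattice (row-major ids)."""
    x = np.array([(-1.0) ** (i + j) for i in range(4) for j in range(4)])
    return x
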