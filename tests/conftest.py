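import numpy as np
import pytest

from tpsc import ExpressionMatrix, PlantedDesign, WeightedNetwork, make_planted_network


@pytest.fixture
def toy_expression():
    """3 genes x 5 samples, fixed values for correlation oracles."""
    values = np.array(
        [
            [1.0, 2.0, 3.0, 4.0, 5.0],
            [2.1, 3.9, 6.2, 8.1, 9.9],
            [5.0, 1.0, 4.0, 2.0, 3.0],
        ]
    )
    return ExpressionMatrix(["gA", "gB", "gC"], [f"s{i}" for i in range(5)], values)


@pytest.fixture
def two_clique_network():
    """Two 3-cliques: within |w| = 0.9, between |w| = 0.1, r = 0.3."""
    design = PlantedDesign(block_sizes=[3, 3], within_cor=0.9, between_cor=0.1)
    net, labels = make_planted_network(design, r=0.3)
    return net, labels


@pytest.fixture
def star_network():
    """5-node star: hub-leaf weight 0.9, leaf-leaf 0.1, r = 0.3."""
    n = 5
    W = np.full((n, n), 0.1)
    W[0, :] = W[:, 0] = 0.9
    np.fill_diagonal(W, 0.0)
    return WeightedNetwork([f"n{i}" for i in range(n)], W, r=0.3)


def random_network(rng, n, unit_mass=False):
    """Random symmetric weights in (-1, 1) and masses in (0, 1]."""
    W = rng.uniform(-0.95, 0.95, size=(n, n))
    W = (W + W.T) / 2
    np.fill_diagonal(W, 0.0)
    mass = None if unit_mass else rng.uniform(0.05, 1.0, size=n)
    return WeightedNetwork([f"n{i}" for i in range(n)], W, mass=mass, r=0.3)
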