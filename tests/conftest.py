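import numpy as np
import pytest

import lw25


@pytest.fixture(scope="session")
def sixitem():
    return lw25.sixitem_fixture()


@pytest.fixture(scope="session")
def demo_grid(sixitem):
    """The five-point demonstration grid at -2..2."""
    return lw25.make_grid(sixitem.model, Q=5, bounds=(-2.0, 2.0))


@pytest.fixture(scope="session")
def sixitem_combos(sixitem, demo_grid):
    """Score-combination posteriors for focal cluster 1 of the six-item scale."""
    return lw25.combo_posteriors(sixitem.model, 1, demo_grid)


@pytest.fixture(scope="session")
def elpa():
    return lw25.elpa21_fixture()


@pytest.fixture(scope="session")
def elpa_grid(elpa):
    return lw25.make_grid(elpa.model, Q=elpa.grid_Q, bounds=elpa.grid_bounds)


@pytest.fixture(scope="session")
def elpa_combos(elpa, elpa_grid):
    """Combination posteriors for the lower grade band (focal cluster 1)."""
    return lw25.combo_posteriors(elpa.model, 1, elpa_grid)


# ------------------------------------------------------------------
# printed worked-example values (six-item scale, Q=5 demonstration grid)
# ------------------------------------------------------------------

# within-cluster summed-score-0 likelihoods at (eta, xi) nodes
# (-2,-2), (-2,-1), (-2,0), (0,0), (2,0), (2,1), (2,2)
STAGE1_SCORE0 = {
    1: [0.989, 0.970, 0.922, 0.472, 0.028, 0.005, 0.001],
    2: [0.947, 0.887, 0.773, 0.248, 0.014, 0.003, 0.001],
    3: [0.922, 0.773, 0.472, 0.095, 0.007, 0.001, 0.000],
}
STAGE1_NODES = [(-2, -2), (-2, -1), (-2, 0), (0, 0), (2, 0), (2, 1), (2, 2)]

# marginalized cluster tables over the eta grid -2..2
MARGINAL = {
    (2, 0): [0.742, 0.519, 0.277, 0.106, 0.028],
    (2, 1): [0.230, 0.375, 0.446, 0.375, 0.230],
    (2, 2): [0.028, 0.106, 0.277, 0.519, 0.742],
    (3, 0): [0.469, 0.302, 0.166, 0.077, 0.029],
    (3, 1): [0.364, 0.396, 0.364, 0.285, 0.192],
    (3, 2): [0.166, 0.302, 0.469, 0.638, 0.779],
}

# rest-score likelihoods for focal cluster 1
REST_CLUSTER1 = {
    0: [0.348, 0.157, 0.046, 0.008, 0.001],
    1: [0.378, 0.319, 0.175, 0.059, 0.012],
    2: [0.220, 0.337, 0.339, 0.214, 0.088],
    3: [0.049, 0.155, 0.310, 0.387, 0.321],
    4: [0.005, 0.032, 0.130, 0.331, 0.578],
}

# combination summaries: (s1, s_rest) -> (prob, mu0, s00, mu1, s11, s01)
COMBO_SUMMARIES = {
    (0, 0): (0.054, -1.136, 0.488, -0.232, 0.815, -0.091),
    (1, 0): (0.019, -0.640, 0.528, 0.413, 0.756, -0.148),
    (2, 0): (0.005, -0.168, 0.513, 0.930, 0.640, -0.150),
    (0, 1): (0.111, -0.812, 0.540, -0.296, 0.796, -0.113),
    (1, 1): (0.053, -0.304, 0.533, 0.315, 0.754, -0.162),
    (2, 1): (0.019, 0.162, 0.519, 0.832, 0.664, -0.156),
    (0, 2): (0.146, -0.477, 0.560, -0.370, 0.775, -0.131),
    (1, 2): (0.096, 0.025, 0.536, 0.212, 0.753, -0.172),
    (2, 2): (0.046, 0.492, 0.527, 0.732, 0.688, -0.159),
    (0, 3): (0.110, -0.091, 0.552, -0.466, 0.750, -0.144),
    (1, 3): (0.101, 0.392, 0.531, 0.092, 0.752, -0.177),
    (2, 3): (0.067, 0.850, 0.511, 0.624, 0.711, -0.151),
    (0, 4): (0.050, 0.302, 0.545, -0.573, 0.725, -0.155),
    (1, 4): (0.064, 0.771, 0.519, -0.036, 0.751, -0.175),
    (2, 4): (0.059, 1.205, 0.456, 0.521, 0.731, -0.131),
}


def node_index(demo_grid, eta, xi):
    """Column index of (eta, xi) in a (K, Qx) stage-I table on the demo grid."""
    k = int(np.where(demo_grid.points[0] == eta)[0][0])
    q = int(np.where(demo_grid.points[0] == xi)[0][0])
    return k, q
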