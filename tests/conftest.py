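import numpy as np
import pandas as pd
import pytest

import progeni as pg


@pytest.fixture
def two_node_net():
    return pg.GeneNetwork.from_edges([("g1", "g2", 2.0)])


@pytest.fixture
def triangle_net():
    return pg.GeneNetwork.from_edges(
        [("g1", "g2", 1.0), ("g2", "g3", 1.0), ("g1", "g3", 1.0)]
    )


@pytest.fixture
def star_net():
    """K_{1,3}: hub g0 connected to three leaves."""
    return pg.GeneNetwork.from_edges(
        [("g0", "g1", 1.0), ("g0", "g2", 1.0), ("g0", "g3", 1.0)]
    )


def random_network(seed: int, n_max: int = 200) -> pg.GeneNetwork:
    """Random connected weighted network with 5..n_max nodes."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(5, n_max + 1))
    return pg.generate_network(
        n, model="scale_free", seed=int(rng.integers(2**31 - 1))
    )


@pytest.fixture(scope="session")
def hidden_instance():
    """One hidden-driver dataset at generator defaults (seed 4)."""
    net = pg.generate_network(500, seed=4)
    X, d, truth = pg.generate_dataset(net, seed=4)
    Xn = pg.normalize_expression(X, log2_first=False)
    return net, Xn, d, truth


@pytest.fixture(scope="session")
def small_instance():
    """Small dataset for fast pipeline tests (150 genes, 40 samples)."""
    net = pg.generate_network(150, seed=7)
    X, d, truth = pg.generate_dataset(
        net, n_samples=40, scenario="direct_drivers", seed=7
    )
    Xn = pg.normalize_expression(X, log2_first=False)
    return net, Xn, d, truth


def zscored_frame(values, samples=None, genes=None) -> pg.ExpressionMatrix:
    """Wrap a raw array as a normalized ExpressionMatrix (columns z-scored)."""
    values = np.asarray(values, dtype=float)
    n, g = values.shape
    samples = samples or [f"s{i}" for i in range(n)]
    genes = genes or [f"g{j}" for j in range(g)]
    X = pg.ExpressionMatrix(
        data=pd.DataFrame(values, index=samples, columns=genes), stage="raw"
    )
    return pg.normalize_expression(X, log2_first=False)
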