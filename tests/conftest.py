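import numpy as np
import pytest

from netprio import FunctionalNetwork, FixtureConfig, generate_network


@pytest.fixture
def toy_net() -> FunctionalNetwork:
    """5-node network with hand-listed weights (adjacency known by table)."""
    edges = {
        ("g1", "g2"): 0.8,
        ("g1", "g3"): 0.3,
        ("g2", "g3"): 0.5,
        ("g3", "g4"): 0.9,
        ("g4", "g5"): 0.2,
    }
    return FunctionalNetwork(edges)


@pytest.fixture(scope="session")
def small_planted():
    """300-gene network with one planted 60-gene module, plus its truth."""
    cfg = FixtureConfig(
        n_genes=300,
        n_modules=1,
        module_size=60,
        mean_degree=20,
        n_snps=100,
        locus=("chr1", 1_000_000, 6_000_000),
        seed=7,
    )
    net, truth = generate_network(cfg)
    return cfg, net, truth


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
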