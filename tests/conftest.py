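import numpy as np
import pytest

from nsin import (
    SignedDigraph,
    SimulationConfig,
    SyntheticNetworkParams,
    cascade,
    fig1_motif,
    random_signed_network,
    read_network,
    weight_all_edges,
)


@pytest.fixture
def motif() -> SignedDigraph:
    return fig1_motif()


@pytest.fixture
def chain3() -> SignedDigraph:
    return cascade(3)


@pytest.fixture
def mek_chain() -> SignedDigraph:
    return read_network(["A\tMEK\t+1", "MEK\tERK\t+1"])


@pytest.fixture
def hepatocyte():
    return random_signed_network(
        SyntheticNetworkParams(n_nodes=40, n_ligands=7, edge_density=0.06,
                               inhibitor_fraction=0.15, seed=11)
    )


def small_random_graph(seed: int, n: int = 12, density: float = 0.2) -> SignedDigraph:
    """Seeded random signed digraph without the ligand/reachability constraints
    (direct Bernoulli adjacency; used as raw material for oracles)."""
    rng = np.random.default_rng(seed)
    g = SignedDigraph()
    names = [f"n{k}" for k in range(n)]
    for name in names:
        g.add_node(name)
    for u in names:
        for v in names:
            if u != v and rng.random() < density:
                g.add_edge(u, v, -1 if rng.random() < 0.2 else +1)
    return g


def quick_config(**kwargs) -> SimulationConfig:
    base = dict(sources={"v1": 1.0}, iterations=50, seed=0, noise_amplitude=0.0)
    base.update(kwargs)
    return SimulationConfig(**base)


@pytest.fixture
def weighted_chain(chain3):
    return chain3, weight_all_edges(chain3)
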