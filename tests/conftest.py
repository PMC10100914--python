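import networkx as nx
import numpy as np
import pandas as pd
import pytest

import seepnet as sp


def edge_set(net) -> set:
    """Unordered edge set of an InteractionNetwork or nx.Graph."""
    graph = net.graph if hasattr(net, "graph") else net
    return {frozenset((u, v)) for u, v in graph.edges}


def random_graph(n: int, p: float, seed: int) -> nx.Graph:
    return nx.gnp_random_graph(n, p, seed=seed)


@pytest.fixture(scope="session")
def toy_counts() -> sp.CountTable:
    """Hand-sized mixed-domain table used across preprocessing tests."""
    frame = pd.DataFrame(
        {
            "b1": [10, 20, 30],
            "b2": [0, 0, 5],
            "a1": [5, 5, 5],
            "f1": [100, 50, 25],
            "f2": [1, 0, 0],
        },
        index=["s1", "s2", "s3"],
    )
    return sp.CountTable(
        counts=frame,
        domain_of={"b1": "bacteria", "b2": "bacteria", "a1": "archaea",
                   "f1": "fungus", "f2": "fungus"},
        marker_of={"b1": "16S", "b2": "16S", "a1": "16S",
                   "f1": "18S", "f2": "18S"},
    )


@pytest.fixture(scope="session")
def fungal_signal():
    """Planted two-taxon balance signal in a 30-taxon fungal community."""
    truth = sp.make_true_model(30, 0.03, domain_fractions={"fungus": 1.0}, seed=7)
    counts = sp.simulate_counts(truth, 200, seed=8)
    planted, signal = sp.plant_balance_signal(counts, {"t1"}, {"t2"}, 2.0, seed=9)
    return planted, signal
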