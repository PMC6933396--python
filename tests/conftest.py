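import sys
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

import omicsnet as on


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_config():
    """Scaled-down study conditions for fast unit tests."""
    return on.default_config(seed=7, n_genes=400, n_planted=20, network_nodes=200)


@pytest.fixture
def toy_counts():
    """A tiny 4-gene, 2x3 count matrix with explicit condition labels."""
    values = pd.DataFrame(
        {
            "ctrl_1": [100, 50, 10, 0],
            "ctrl_2": [110, 55, 12, 0],
            "ctrl_3": [90, 45, 9, 0],
            "case_1": [400, 50, 11, 0],
            "case_2": [380, 52, 10, 0],
            "case_3": [420, 48, 12, 0],
        },
        index=["GA", "GB", "GC", "GD"],
    )
    conds = {s: s.rsplit("_", 1)[0] for s in values.columns}
    return on.OmicsMatrix(values=values, conditions=conds, kind="counts")


def random_gnp_graph(n: int, p: float, rng: np.random.Generator) -> nx.Graph:
    """Seeded G(n, p) over string node labels."""
    g = nx.Graph()
    nodes = [f"n{i:02d}" for i in range(n)]
    g.add_nodes_from(nodes)
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                g.add_edge(nodes[i], nodes[j])
    return g
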