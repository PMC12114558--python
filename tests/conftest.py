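import networkx as nx
import numpy as np
import pandas as pd
import pytest

from pahsoil import synth
from pahsoil.community import AbundanceTable


@pytest.fixture(scope="session")
def small_config():
    """A reduced study: 3 regions x 2 covers x 5 samples, 60 genera."""
    return synth.StudyConfig(samples_per_cell=5, n_genera=60, seed=7)


@pytest.fixture(scope="session")
def small_study(small_config):
    return synth.generate_study(small_config, seed=7)


@pytest.fixture(scope="session")
def default_study():
    return synth.generate_study(synth.StudyConfig(), seed=1)


@pytest.fixture
def toy_table():
    """5 genera in 2 phyla across 3 samples, counts mode."""
    data = pd.DataFrame(
        {
            "s1": [4, 1, 0, 3, 2],
            "s2": [0, 5, 5, 0, 0],
            "s3": [1, 1, 1, 1, 6],
        },
        index=[f"t{i}" for i in range(1, 6)],
    )
    tax = pd.Series(
        [
            "k__Bacteria;p__Proteobacteria;c__;o__;f__;g__GenA",
            "k__Bacteria;p__Proteobacteria;c__;o__;f__;g__GenB",
            "k__Bacteria;p__Proteobacteria;c__;o__;f__;g__GenC",
            "k__Bacteria;p__Firmicutes;c__;o__;f__;g__GenD",
            "k__Bacteria;p__Firmicutes;c__;o__;f__;g__GenE",
        ],
        index=data.index,
    )
    return AbundanceTable(data=data, taxonomy=tax, mode="counts")


@pytest.fixture
def two_clique_graph():
    """Two K4 cliques joined by a single bridge edge (13 edges total)."""
    g = nx.Graph()
    for offset in (0, 4):
        for i in range(4):
            for j in range(i + 1, 4):
                g.add_edge(offset + i, offset + j)
    g.add_edge(0, 4)
    return g


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
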