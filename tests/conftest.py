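import math

import pytest

from gosim import MeasureContext
from gosim.fixtures import (
    DagSpec,
    fixture_chain,
    fixture_diamond,
    fixture_helicase,
    random_corpus,
    random_dag,
)

LN2 = math.log(2.0)
LN3 = math.log(3.0)
LN4 = math.log(4.0)
LN32 = math.log(1.5)  # ln(3/2)


@pytest.fixture(scope="session")
def diamond():
    """The five-term diamond DAG with its three-protein corpus."""
    return fixture_diamond()


@pytest.fixture(scope="session")
def diamond_graph(diamond):
    return diamond[0]


@pytest.fixture(scope="session")
def diamond_corpus(diamond):
    return diamond[1]


@pytest.fixture(scope="session")
def ann_ctx(diamond):
    graph, corpus = diamond
    return MeasureContext(graph, "annotation", corpus)


@pytest.fixture(scope="session")
def uni_ctx(diamond_graph):
    return MeasureContext(diamond_graph, "universal")


@pytest.fixture(scope="session")
def zhang_ctx(diamond_graph):
    return MeasureContext(diamond_graph, "zhang")


@pytest.fixture(scope="session")
def wang_ctx(diamond_graph):
    return MeasureContext(diamond_graph, "wang")


@pytest.fixture(scope="session")
def chain_graph():
    return fixture_chain()


@pytest.fixture(scope="session")
def helicase_graph():
    return fixture_helicase()


@pytest.fixture(scope="session")
def small_random_dags():
    """A family of seeded random DAGs with matching corpora."""
    out = []
    for seed in range(8):
        g = random_dag(DagSpec(n_terms=30, seed=seed))
        out.append((g, random_corpus(g, n_proteins=15, seed=seed)))
    return out
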