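import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from canspec.io_formats import MutationSignificanceTable, OntologyGraph
import networkx as nx

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def small_table() -> MutationSignificanceTable:
    """Five genes, three tumor types, with one clear specific and one
    clear general gene."""
    q = pd.DataFrame(
        {
            "T1": [1e-10, 0.5, 1e-6, 0.9, 0.3],
            "T2": [0.8, 0.4, 1e-7, 0.7, 0.2],
            "T3": [0.9, 0.6, 1e-9, 0.8, 0.4],
        },
        index=pd.Index(["spec1", "bg1", "gen1", "bg2", "bg3"], name="gene"),
    )
    pan = pd.Series(
        [0.9, 0.7, 1e-11, 0.8, 0.6], index=q.index, name="pan_q"
    )
    return MutationSignificanceTable(q=q, pan_q=pan)


@pytest.fixture
def chain_ontology() -> OntologyGraph:
    """Root <- A <- B chain plus a sibling C under the root.

    Annotation frequencies (4 genes): root 4/4, A 2/4, B 1/4, C 1/4,
    so IC(A) = 1 bit, IC(B) = IC(C) = 2 bits.
    """
    g = nx.DiGraph()
    for node in ("R", "A", "B", "C"):
        g.add_node(node, name=node, namespace="bp")
    g.add_edge("A", "R")
    g.add_edge("B", "A")
    g.add_edge("C", "R")
    annotations = {
        "g1": frozenset({"B"}),
        "g2": frozenset({"A"}),
        "g3": frozenset({"C"}),
        "g4": frozenset({"R"}),
    }
    return OntologyGraph(graph=g, annotations=annotations)


@pytest.fixture
def scored_frame() -> pd.DataFrame:
    """Minimal ranked specificity table for enrichment tests."""
    genes = [f"g{i}" for i in range(1, 6)]
    return pd.DataFrame(
        {
            "score": [1.0, 2.0, 3.0, 4.0, 5.0],
            "rank": [1, 2, 3, 4, 5],
        },
        index=pd.Index(genes, name="gene"),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20160209)
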