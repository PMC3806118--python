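import networkx as nx
import numpy as np
import pandas as pd
import pytest

from lactmir import ontology
from lactmir.io_tables import ReadCountTable


def build_ontology(edges, namespaces=None, names=None):
    """OntologyGraph from (child, parent) edge pairs; single-namespace by
    default."""
    graph = nx.DiGraph()
    nodes = {n for e in edges for n in e}
    graph.add_nodes_from(nodes)
    graph.add_edges_from(edges)
    namespaces = namespaces or {n: "biological_process" for n in graph.nodes}
    names = names or {n: n for n in graph.nodes}
    return ontology._finalize(graph, names, namespaces)


def random_dag(rng, n_terms=30, p_extra=0.3):
    """Random rooted DAG (child -> parent) for oracle comparisons."""
    ids = [f"GO:{i:07d}" for i in range(n_terms)]
    edges = []
    for i in range(1, n_terms):
        parent = ids[int(rng.integers(i))]
        edges.append((ids[i], parent))
        if rng.random() < p_extra and i >= 2:
            extra = ids[int(rng.integers(i))]
            if extra != parent:
                edges.append((ids[i], extra))
    return build_ontology(edges)


def make_counts(data, totals):
    """ReadCountTable from {mirna: {stage: count}} and {stage: total}."""
    frame = pd.DataFrame(data).T.astype("int64")
    frame.index.name = "miRNA"
    return ReadCountTable(counts=frame, total_clean_reads=dict(totals))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
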