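import numpy as np
import pandas as pd
import pytest

import networkx as nx

from regulomeshift.bpnet import BipartiteNet, GENE_PART, BP_PART
from regulomeshift.io_tables import AnnotationTable, ExpressionMatrix


def make_net(edges, condition="WT"):
    """Build a BipartiteNet from (gene, bp, weight) triples."""
    g = nx.DiGraph()
    for gene, bp, w in edges:
        g.add_node(gene, part=GENE_PART)
        g.add_node(bp, part=BP_PART)
        g.add_edge(gene, bp, weight=float(w))
    return BipartiteNet(condition=condition, graph=g)


def random_bipartite_net(rng, max_genes=6, max_bps=6, connected=True):
    """Random connected weighted bipartite network (for oracle tests)."""
    while True:
        n_genes = int(rng.integers(2, max_genes + 1))
        n_bps = int(rng.integers(1, max_bps + 1))
        genes = [f"g{i}" for i in range(n_genes)]
        bps = [f"b{j}" for j in range(n_bps)]
        edges = []
        for g in genes:
            k = int(rng.integers(1, n_bps + 1))
            for b in rng.choice(bps, size=k, replace=False):
                edges.append((g, str(b), float(rng.uniform(0.1, 10.0))))
        net = make_net(edges)
        if not connected:
            return net
        und = net.graph.to_undirected()
        if und.number_of_nodes() and nx.is_connected(und):
            return net


@pytest.fixture
def toy_matrix():
    values = pd.DataFrame(
        {
            "WT_1": [2.0, 10.0, 0.0],
            "WT_2": [4.0, 12.0, 0.0],
            "KO_1": [6.0, 5.0, 8.0],
            "KO_2": [8.0, 7.0, 10.0],
        },
        index=["gA", "gB", "gC"],
    )
    cond = {"WT_1": "WT", "WT_2": "WT", "KO_1": "KO", "KO_2": "KO"}
    return ExpressionMatrix(values, cond)


@pytest.fixture
def toy_annotations():
    rec = pd.DataFrame(
        [
            ("gA", "GO:0000001", "proc one"),
            ("gA", "GO:0000002", "proc two"),
            ("gB", "GO:0000002", "proc two"),
            ("gC", "GO:0000003", "proc three"),
        ],
        columns=["gene_id", "term_id", "term_name"],
    )
    return AnnotationTable(rec)


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
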