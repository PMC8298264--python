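"""Weighted bipartite gene->process networks and centrality-shift analysis.

Each condition (wildtype or knockdown) yields a directed bipartite network:
genes are sources, the biological processes (BPs) they are annotated to are
targets, and every edge carries the gene's mean expression in that condition
("representation") as its weight.  Node importance is the eigenvector
centrality of the symmetrized weighted adjacency, max-rescaled so the top
node scores exactly 1; "relative importance" is that score as a percentage.

The per-gene rate of change of centrality between the two condition networks,
R = 100*(c_KO - c_WT)/c_WT, drives two classifications: candidate functional
complements (R above a large threshold, by default +1000%, and up-regulated)
and reduced-importance genes (relative importance in the knockdown network
below a small threshold, by default 1%).

Centrality is computed on the symmetrized adjacency because in a strictly
gene->BP directed graph every gene has zero in-degree, which collapses
directed eigenvector centrality to zero on all gene nodes.  Direction is
retained in the data model and in GraphML exports.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .io_tables import AnnotationTable

logger = logging.getLogger(__name__)

GENE_PART = "gene"
BP_PART = "bp"

DEFAULT_INCREASE_THRESHOLD = 1000.0  # percent
DEFAULT_REDUCED_THRESHOLD = 1.0  # percent

LABEL_UNCLASSIFIED = "unclassified"
LABEL_COMPLEMENT = "functional_complement"
LABEL_REDUCED = "reduced_importance"
LABEL_NOVEL = "novel_in_ko"
LABEL_ABSENT = "absent_in_ko"


class ConvergenceError(RuntimeError):
    """Power iteration failed to converge within the iteration budget."""


@dataclass
class BipartiteNet:
    """Directed weighted bipartite network for one condition."""

    condition: str
    graph: nx.DiGraph

    def __post_init__(self) -> None:
        for u, v, w in self.graph.edges(data="weight"):
            if self.graph.nodes[u].get("part") != GENE_PART or \
                    self.graph.nodes[v].get("part") != BP_PART:
                raise ValueError(f"edge {u!r}->{v!r} is not gene->bp")
            if not (w is not None and math.isfinite(w) and w > 0):
                raise ValueError(f"edge {u!r}->{v!r} weight must be positive")

    @property
    def gene_nodes(self) -> set[str]:
        return {n for n, p in self.graph.nodes(data="part")
                if p == GENE_PART}

    @property
    def bp_nodes(self) -> set[str]:
        return {n for n, p in self.graph.nodes(data="part") if p == BP_PART}

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def undirected(self) -> nx.Graph:
        """Symmetrized weighted view used for centrality and clustering."""
        return self.graph.to_undirected(as_view=False)


@dataclass
class NodeCentrality:
    node: str
    eig_centrality: float  # max-normalized, in [0, 1]
    weighted_degree: float

    @property
    def relative_importance(self) -> float:
        return 100.0 * self.eig_centrality


@dataclass
class CommunityPartition:
    membership: dict[str, int]
    modularity: float

    @property
    def n_communities(self) -> int:
        return len(set(self.membership.values()))


def build_network(
    means,
    ann: AnnotationTable,
    condition: str = "WT",
    min_weight: float = 0.0,
    transform: str = "log2",
) -> BipartiteNet:
    """Build the per-condition bipartite network.

    ``means`` maps gene id -> mean expression in this condition.  One edge
    is created per (gene, annotated BP) pair, weighted by the gene's
    representation: ``log2(1 + mean)`` by default, or the raw mean with
    ``transform="linear"``.  The log representation keeps edge weights on a
    common scale; raw heavy-tailed abundances can concentrate the dominant
    eigenvector onto the single strongest gene star, which degenerates the
    downstream centrality comparison.  Genes with mean expression <=
    ``min_weight`` are excluded; BPs enter the network only through
    incident edges.  Annotation rows for genes absent from ``means`` are
    dropped (count logged).
    """
    if transform not in ("log2", "linear"):
        raise ValueError(f"unknown representation transform {transform!r}")
    if hasattr(means, "items"):
        means = dict(means.items())
    g = nx.DiGraph()
    dropped = 0
    for _, row in ann.records.iterrows():
        gene, term = row["gene_id"], row["term_id"]
        if gene not in means:
            dropped += 1
            continue
        w = float(means[gene])
        if w < 0:
            raise ValueError(f"negative representation for gene {gene!r}")
        if w <= min_weight:
            continue
        if transform == "log2":
            w = float(np.log2(1.0 + w))
        g.add_node(gene, part=GENE_PART)
        g.add_node(term, part=BP_PART, name=row["term_name"])
        g.add_edge(gene, term, weight=w)
    if dropped:
        logger.info("build_network(%s): dropped %d annotation rows for "
                    "genes absent from the expression data", condition,
                    dropped)
    return BipartiteNet(condition=condition, graph=g)


def weighted_degree(net: BipartiteNet, node: str) -> float:
    """Sum of incident edge weights: out-weights for genes, in for BPs."""
    if node not in net.graph:
        raise KeyError(f"node {node!r} not in network")
    if net.graph.nodes[node].get("part") == GENE_PART:
        return float(net.graph.out_degree(node, weight="weight"))
    return float(net.graph.in_degree(node, weight="weight"))


def _adjacency(net: BipartiteNet, weighted: bool):
    nodes = sorted(net.graph.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    a = np.zeros((len(nodes), len(nodes)))
    for u, v, w in net.graph.edges(data="weight"):
        val = float(w) if weighted else 1.0
        a[index[u], index[v]] = val
        a[index[v], index[u]] = val
    return nodes, a


def eigenvector_centrality(
    net: BipartiteNet,
    weighted: bool = True,
    tol: float = 1e-10,
    max_iter: int = 20000,
) -> dict[str, NodeCentrality]:
    """Eigenvector centrality on the symmetrized (un)weighted adjacency.

    Power iteration on the shifted matrix A/w_max + sigma*I with L2
    normalization at each step, where w_max is the largest edge weight and
    sigma the largest row sum of the rescaled adjacency.  The shift removes
    the +/-lambda oscillation of bipartite spectra at any weight scale
    without changing eigenvectors (sigma >= spectral radius, so the
    dominant shifted eigenvalue is the one with the largest positive
    unshifted eigenvalue).  The dominant eigenvector is made non-negative
    and max-rescaled so the top node scores exactly 1.  Deterministic: the
    start vector is uniform.
    """
    if net.graph.number_of_nodes() == 0:
        raise ValueError("centrality of an empty network is undefined")
    nodes, a = _adjacency(net, weighted)
    n = len(nodes)
    w_max = a.max()
    if w_max > 0:
        a = a / w_max
    sigma = max(a.sum(axis=1).max(), 1.0)
    v = np.full(n, 1.0 / np.sqrt(n))
    prev_resid = np.inf
    for _ in range(max_iter):
        nxt = a @ v + sigma * v
        norm = np.linalg.norm(nxt)
        if norm == 0.0:
            break  # graph with no edges: uniform vector is stationary
        nxt /= norm
        resid = np.linalg.norm(nxt - v)
        v = nxt
        # geometric-series bound on the remaining error: resid shrinks by
        # ~ratio per step, so the distance to the limit is resid*r/(1-r)
        ratio = resid / prev_resid if np.isfinite(prev_resid) else 1.0
        prev_resid = resid
        if resid == 0.0 or (ratio < 1.0
                            and resid * ratio / (1.0 - ratio) < tol):
            break
    else:
        raise ConvergenceError(
            f"power iteration did not converge in {max_iter} steps "
            f"(last residual {resid:.3e})"
        )
    v = np.abs(v)
    v /= v.max()
    return {
        node: NodeCentrality(node, float(v[i]), weighted_degree(net, node))
        for i, node in enumerate(nodes)
    }


def centrality_rate_of_change(
    wt: dict[str, NodeCentrality],
    ko: dict[str, NodeCentrality],
    nodes: set[str] | None = None,
) -> pd.DataFrame:
    """Per-gene centrality shift between the two condition networks.

    R = 100*(c_KO - c_WT)/c_WT when the gene is present in both networks.
    Genes present only in the knockdown network are labelled ``novel_in_ko``
    with ``R = +inf``; genes absent from the knockdown network are labelled
    ``absent_in_ko`` with ``R = -100``.  ``nodes`` restricts the report,
    typically to the union of the gene parts of the two networks so that BP
    nodes are not reported as genes.
    """
    wt_keys = set(wt)
    ko_keys = set(ko)
    if nodes is not None:
        wt_keys &= nodes
        ko_keys &= nodes
    rows = []
    for gene in sorted(wt_keys | ko_keys):
        c_wt = wt[gene].eig_centrality if gene in wt_keys else np.nan
        c_ko = ko[gene].eig_centrality if gene in ko_keys else np.nan
        if gene not in wt_keys:
            rate, label = np.inf, LABEL_NOVEL
        elif gene not in ko_keys:
            rate, label = -100.0, LABEL_ABSENT
        elif c_wt > 0:
            rate, label = 100.0 * (c_ko - c_wt) / c_wt, LABEL_UNCLASSIFIED
        else:
            rate = np.inf if c_ko > 0 else 0.0
            label = LABEL_UNCLASSIFIED
        rows.append((gene, c_wt, c_ko, rate, label))
    return pd.DataFrame(
        rows, columns=["gene_id", "c_wt", "c_ko", "rate_of_change", "label"]
    )


def classify_functional_complements(
    report: pd.DataFrame,
    de: pd.DataFrame,
    increase_threshold: float = DEFAULT_INCREASE_THRESHOLD,
    require_up: bool = True,
) -> set[str]:
    """Genes whose centrality rose more than ``increase_threshold`` percent.

    Genes newly appearing in the knockdown network (``novel_in_ko``) qualify
    by definition.  With ``require_up`` (default) the gene must also be
    up-regulated (log2 fold change > 0) in the differential-expression
    results.
    """
    gains = report[
        (report["label"] == LABEL_NOVEL)
        | (report["rate_of_change"] > increase_threshold)
    ]
    candidates = set(gains["gene_id"])
    if require_up:
        lfc = de.set_index("gene_id")["log2fc"]
        candidates = {g for g in candidates if lfc.get(g, 0.0) > 0.0}
    return candidates


def classify_reduced_importance(
    ko: dict[str, NodeCentrality],
    threshold_pct: float = DEFAULT_REDUCED_THRESHOLD,
    gene_nodes: set[str] | None = None,
) -> set[str]:
    """Genes whose knockdown-network relative importance is below threshold.

    Strict inequality: a gene at exactly ``threshold_pct`` is excluded.
    """
    out = set()
    for node, c in ko.items():
        if gene_nodes is not None and node not in gene_nodes:
            continue
        if c.relative_importance < threshold_pct:
            out.add(node)
    return out


def apply_classifications(
    report: pd.DataFrame,
    complements: set[str],
    reduced: set[str],
) -> pd.DataFrame:
    """Stamp mutually exclusive labels into a rate-of-change report.

    Sentinel labels (``novel_in_ko``/``absent_in_ko``) are kept, except that
    a novel gene classified as a complement is labelled as such; a gene
    qualifying as both complement and reduced is labelled complement (the
    centrality gain is the stronger signal).
    """
    out = report.copy()
    for i, row in out.iterrows():
        g = row["gene_id"]
        if g in complements:
            out.at[i, "label"] = LABEL_COMPLEMENT
        elif row["label"] in (LABEL_NOVEL, LABEL_ABSENT):
            continue
        elif g in reduced:
            out.at[i, "label"] = LABEL_REDUCED
    return out


def louvain_communities(
    net: BipartiteNet,
    resolution: float = 1.0,
    seed: int = 0,
) -> CommunityPartition:
    """Louvain modularity clustering on the symmetrized weighted graph.

    Deterministic for a given seed (the seed drives the node-order
    shuffling of the greedy optimization).  The reported modularity is the
    Newman weighted modularity of the returned partition.
    """
    if net.graph.number_of_nodes() == 0:
        raise ValueError("cannot cluster an empty network")
    g = net.undirected()
    comms = nx.community.louvain_communities(
        g, weight="weight", resolution=resolution, seed=seed
    )
    membership = {n: i for i, c in enumerate(comms) for n in c}
    q = nx.community.modularity(g, comms, weight="weight",
                                resolution=resolution)
    return CommunityPartition(membership=membership, modularity=float(q))
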