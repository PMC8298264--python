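import networkx as nx
import numpy as np
import pandas as pd
import pytest

from regulomeshift import bpnet
from regulomeshift.bpnet import (
    build_network,
    centrality_rate_of_change,
    classify_functional_complements,
    classify_reduced_importance,
    eigenvector_centrality,
    louvain_communities,
    weighted_degree,
)
from tests.conftest import make_net, random_bipartite_net


def dense_centrality(net, weighted=True):
    """Oracle: dominant eigenvector by dense symmetric eigendecomposition."""
    nodes = sorted(net.graph.nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    a = np.zeros((len(nodes), len(nodes)))
    for u, v, w in net.graph.edges(data="weight"):
        val = float(w) if weighted else 1.0
        a[idx[u], idx[v]] = a[idx[v], idx[u]] = val
    vals, vecs = np.linalg.eigh(a)
    v = np.abs(vecs[:, np.argmax(vals)])
    return {n: v[idx[n]] / v.max() for n in nodes}


class TestBuildNetwork:
    def test_edges_carry_log_representation(self, toy_annotations):
        net = build_network({"gA": 5.0, "gB": 3.0}, toy_annotations)
        assert net.gene_nodes == {"gA", "gB"}
        w = net.graph["gA"]["GO:0000001"]["weight"]
        assert w == pytest.approx(np.log2(6.0))

    def test_linear_transform_keeps_raw_means(self, toy_annotations):
        net = build_network({"gA": 5.0}, toy_annotations,
                            transform="linear")
        assert net.graph["gA"]["GO:0000001"]["weight"] == 5.0

    def test_zero_representation_gene_absent(self, toy_annotations):
        net = build_network({"gA": 0.0, "gB": 2.0}, toy_annotations)
        assert "gA" not in net.graph
        # the BP annotated only to excluded/unknown genes is absent too
        assert "GO:0000003" not in net.graph

    def test_shared_bp_collects_incident_edges(self, toy_annotations):
        net = build_network({"gA": 5.0, "gB": 3.0}, toy_annotations)
        assert net.graph.in_degree("GO:0000002") == 2

    def test_unknown_annotation_genes_dropped(self, toy_annotations):
        net = build_network({"gA": 1.0}, toy_annotations)
        assert net.gene_nodes == {"gA"}


class TestWeightedDegree:
    def test_gene_and_bp_degrees(self):
        net = make_net([("g", "b1", 5), ("g", "b2", 5), ("g", "b3", 5),
                        ("h", "b1", 2)])
        assert weighted_degree(net, "g") == pytest.approx(15.0)
        assert weighted_degree(net, "b1") == pytest.approx(7.0)

    def test_missing_node_raises(self):
        net = make_net([("g", "b", 1)])
        with pytest.raises(KeyError):
            weighted_degree(net, "nope")


class TestEigenvectorCentrality:
    def test_star_has_analytic_scores(self):
        net = make_net([("g1", "b", 1), ("g2", "b", 1), ("g3", "b", 1)])
        c = eigenvector_centrality(net)
        assert c["b"].eig_centrality == pytest.approx(1.0)
        for g in ("g1", "g2", "g3"):
            assert c[g].eig_centrality == pytest.approx(1 / np.sqrt(3),
                                                        abs=1e-9)

    @pytest.mark.parametrize("w", [0.01, 1.0, 1e6])
    def test_single_edge_scores_one_for_both(self, w):
        net = make_net([("g", "b", w)])
        c = eigenvector_centrality(net)
        assert c["g"].eig_centrality == pytest.approx(1.0)
        assert c["b"].eig_centrality == pytest.approx(1.0)

    def test_matches_dense_oracle_on_random_networks(self, rng):
        for _ in range(30):
            net = random_bipartite_net(rng)
            got = eigenvector_centrality(net)
            want = dense_centrality(net)
            for n, c in got.items():
                assert c.eig_centrality == pytest.approx(want[n], abs=1e-8)

    def test_scale_invariance_of_weights(self, rng):
        net = random_bipartite_net(rng)
        base = eigenvector_centrality(net)
        for factor in (0.001, 7.3, 1e5):
            g = net.graph.copy()
            for u, v in g.edges:
                g[u][v]["weight"] *= factor
            scaled = eigenvector_centrality(
                bpnet.BipartiteNet(net.condition, g))
            for n in base:
                assert scaled[n].eig_centrality == pytest.approx(
                    base[n].eig_centrality, abs=1e-10)

    def test_raising_a_gene_weight_does_not_lower_its_centrality(self, rng):
        for _ in range(10):
            net = random_bipartite_net(rng)
            gene = sorted(net.gene_nodes)[0]
            before = eigenvector_centrality(net)[gene].eig_centrality
            g = net.graph.copy()
            for _, v in list(g.out_edges(gene)):
                g[gene][v]["weight"] *= 2.0
            after = eigenvector_centrality(
                bpnet.BipartiteNet(net.condition, g))[gene].eig_centrality
            assert after >= before - 1e-9

    def test_empty_network_rejected(self):
        with pytest.raises(ValueError):
            eigenvector_centrality(make_net([]))


class TestRateOfChange:
    def test_identical_networks_give_zero_rate(self, rng):
        net = random_bipartite_net(rng)
        c = eigenvector_centrality(net)
        rep = centrality_rate_of_change(c, c, nodes=net.gene_nodes)
        assert np.allclose(rep["rate_of_change"], 0.0)

    def test_tenfold_gain_is_plus_1000_percent(self):
        wt = {"g": bpnet.NodeCentrality("g", 0.1, 1.0)}
        ko = {"g": bpnet.NodeCentrality("g", 1.1, 1.0)}
        rep = centrality_rate_of_change(wt, ko)
        assert rep["rate_of_change"].iloc[0] == pytest.approx(1000.0)

    def test_gene_only_in_ko_is_novel(self):
        ko = {"g": bpnet.NodeCentrality("g", 0.5, 1.0)}
        rep = centrality_rate_of_change({}, ko)
        assert rep["label"].iloc[0] == bpnet.LABEL_NOVEL
        assert np.isinf(rep["rate_of_change"].iloc[0])

    def test_gene_absent_in_ko_is_minus_100(self):
        wt = {"g": bpnet.NodeCentrality("g", 0.5, 1.0)}
        rep = centrality_rate_of_change(wt, {})
        assert rep["label"].iloc[0] == bpnet.LABEL_ABSENT
        assert rep["rate_of_change"].iloc[0] == -100.0


def _report(rows):
    return pd.DataFrame(
        rows, columns=["gene_id", "c_wt", "c_ko", "rate_of_change", "label"]
    )


class TestClassifiers:
    def test_complement_requires_threshold_and_direction(self):
        rep = _report([
            ("up_big", 0.01, 0.2, 1500.0, "unclassified"),
            ("down_big", 0.01, 0.2, 1500.0, "unclassified"),
            ("up_small", 0.1, 0.2, 100.0, "unclassified"),
        ])
        de = pd.DataFrame({"gene_id": ["up_big", "down_big", "up_small"],
                           "log2fc": [3.0, -1.0, 3.0]})
        assert classify_functional_complements(rep, de) == {"up_big"}
        assert classify_functional_complements(
            rep, de, require_up=False) == {"up_big", "down_big"}

    def test_immune_gene_anchor_set_recovered(self):
        """A report where the known immune-response candidates carry >1000%
        gains and up-regulation yields exactly that gene set."""
        genes = ["IGLL1", "PRG2", "PRTN3", "EPX", "CLC", "CTSG",
                 "KLF2", "RHOB"]
        rates = [1500.0, 1300.0, 1200.0, 1100.0, 1050.0, 1010.0,
                 -99.0, -95.0]
        rep = _report([(g, 0.01, 0.1, r, "unclassified")
                       for g, r in zip(genes, rates)])
        de = pd.DataFrame({"gene_id": genes,
                           "log2fc": [6.4, 5.8, 4.1, 4.0, 3.0, 2.5,
                                      -2.1, -3.0]})
        assert classify_functional_complements(rep, de) == {
            "IGLL1", "PRG2", "PRTN3", "EPX", "CLC", "CTSG"}

    def test_novel_gene_counts_as_complement_when_up(self):
        rep = _report([("novel", np.nan, 0.5, np.inf, bpnet.LABEL_NOVEL)])
        de = pd.DataFrame({"gene_id": ["novel"], "log2fc": [4.0]})
        assert classify_functional_complements(rep, de) == {"novel"}

    def test_reduced_importance_is_strictly_below_threshold(self):
        ko = {
            "klf2": bpnet.NodeCentrality("klf2", 0.0091, 1.0),
            "edge": bpnet.NodeCentrality("edge", 0.01, 1.0),
            "hub": bpnet.NodeCentrality("hub", 0.9, 1.0),
        }
        assert classify_reduced_importance(ko) == {"klf2"}
        assert classify_reduced_importance({}) == set()


def brute_force_best_modularity(graph):
    """Enumerate all partitions of the node set (oracle for tiny graphs)."""
    nodes = sorted(graph.nodes)

    def partitions(seq):
        if not seq:
            yield []
            return
        head, rest = seq[0], seq[1:]
        for part in partitions(rest):
            for i in range(len(part)):
                yield part[:i] + [part[i] | {head}] + part[i + 1:]
            yield part + [{head}]

    best = -1.0
    for part in partitions(nodes):
        q = nx.community.modularity(graph, part, weight="weight")
        best = max(best, q)
    return best


class TestLouvain:
    def test_disconnected_stars_split_into_two_communities(self):
        net = make_net([("g1", "b1", 1), ("g2", "b1", 1),
                        ("g3", "b2", 1), ("g4", "b2", 1)])
        part = louvain_communities(net, seed=0)
        assert part.n_communities == 2
        assert part.membership["g1"] == part.membership["g2"]
        assert part.membership["g3"] == part.membership["g4"]

    def test_k22_partition_reaches_brute_force_modularity(self):
        net = make_net([(g, b, 1.0) for g in ("g1", "g2")
                        for b in ("b1", "b2")])
        part = louvain_communities(net, seed=0)
        best = brute_force_best_modularity(net.undirected())
        assert part.modularity == pytest.approx(best, abs=1e-12)

    def test_same_seed_same_partition(self, rng):
        net = random_bipartite_net(rng)
        p1 = louvain_communities(net, seed=7)
        p2 = louvain_communities(net, seed=7)
        assert p1.membership == p2.membership

    def test_modularity_at_least_trivial_partition(self, rng):
        for _ in range(5):
            net = random_bipartite_net(rng)
            part = louvain_communities(net, seed=1)
            trivial = nx.community.modularity(
                net.undirected(), [set(net.graph.nodes)], weight="weight")
            assert part.modularity >= trivial - 1e-12
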