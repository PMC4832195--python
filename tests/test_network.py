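"""Correlation-network inference: admission rule, statistics, communities,
generalists and export round trips."""

import math

import networkx as nx
import numpy as np
import pytest
from scipy import stats as sps

import soilnet as sn
from soilnet.io_model import ValidationError
from soilnet.network import CorrelationNetwork

from conftest import make_table


def make_network(edges, categories=None, mode="ion-ion"):
    graph = nx.Graph()
    for u, v, sign in edges:
        graph.add_edge(u, v, r=0.9 if sign == "positive" else -0.9, sign=sign)
    for node in graph.nodes:
        graph.nodes[node]["category"] = (categories or {}).get(node, "ion")
        graph.nodes[node]["degree"] = graph.degree(node)
    return CorrelationNetwork(graph, mode, 0.58, 0.05)


class TestPearsonMatrix:
    def test_perfect_positive_and_negative(self):
        table = make_table(np.array([[1, 1, 3], [2, 2, 2], [3, 3, 1], [4, 4, 0]]).T)
        # columns: [1,2,3,4], [1,2,3,4], [3,2,1,0]
        corr = sn.pearson_matrix(make_table(
            np.array([[1.0, 1.0, 3.0], [2, 2, 2], [3, 3, 1], [4, 4, 0]])
        ))
        assert corr.r[0, 1] == pytest.approx(1.0)
        assert corr.r[0, 2] == pytest.approx(-1.0)
        assert corr.p[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_hand_evaluated_r(self):
        values = np.array([[1.0, 1.0], [2, 3], [3, 2], [4, 4]])
        corr = sn.pearson_matrix(make_table(values))
        assert corr.r[0, 1] == pytest.approx(0.8, abs=1e-12)

    def test_matches_scipy_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            values = rng.random((10, 4))
            corr = sn.pearson_matrix(make_table(values))
            for i in range(4):
                for j in range(i + 1, 4):
                    r_ref, p_ref = sps.pearsonr(values[:, i], values[:, j])
                    assert corr.r[i, j] == pytest.approx(r_ref, abs=1e-9)
                    assert corr.p[i, j] == pytest.approx(p_ref, abs=1e-9)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValidationError, match=">= 4 samples"):
            sn.pearson_matrix(make_table(np.ones((3, 2))))

    def test_zero_variance_variable_dropped(self):
        rng = np.random.default_rng(1)
        values = rng.random((8, 3))
        values[:, 1] = 5.0
        corr = sn.pearson_matrix(make_table(values))
        assert corr.dropped == ("v1",)
        assert corr.variable_ids == ("v0", "v2")


class TestBuildNetwork:
    @pytest.fixture(scope="class")
    def mixed_corr(self):
        ids = ("e1", "e2", "i1", "i2")
        cats = ("enzyme", "enzyme", "ion", "ion")
        r = np.array([
            [1.0, 0.9, -0.9, 0.2],
            [0.9, 1.0, 0.7, 0.9],
            [-0.9, 0.7, 1.0, 0.9],
            [0.2, 0.9, 0.9, 1.0],
        ])
        p = np.full((4, 4), 0.001)
        np.fill_diagonal(p, 0.0)
        return sn.CorrelationResult(ids, cats, r, p, n_obs=12)

    def test_high_cutoff_gives_empty_network(self, mixed_corr):
        net = sn.build_network(mixed_corr, r_cutoff=0.95, mode="all")
        assert net.n_edges == 0 and net.n_nodes == 0

    def test_clear_admission_positive(self, mixed_corr):
        net = sn.build_network(mixed_corr, mode="all")
        assert net.graph.edges[("e1", "e2")]["sign"] == "positive"

    def test_negative_correlation_admitted_by_absolute_rule(self, mixed_corr):
        net = sn.build_network(mixed_corr, mode="all")
        assert net.graph.has_edge("e1", "i1")
        assert net.graph.edges[("e1", "i1")]["sign"] == "negative"
        # brute-force scan of the matrix agrees with the admitted edge set
        expected = {
            frozenset((mixed_corr.variable_ids[i], mixed_corr.variable_ids[j]))
            for i in range(4) for j in range(i + 1, 4)
            if abs(mixed_corr.r[i, j]) > 0.58 and mixed_corr.p[i, j] < 0.05
        }
        assert {frozenset(e) for e in net.graph.edges} == expected

    def test_mode_eligibility(self, mixed_corr):
        enzyme_ion = sn.build_network(mixed_corr, mode="enzyme-ion")
        for u, v in enzyme_ion.graph.edges:
            cats = {enzyme_ion.graph.nodes[u]["category"],
                    enzyme_ion.graph.nodes[v]["category"]}
            assert cats == {"enzyme", "ion"}
        ion_ion = sn.build_network(mixed_corr, mode="ion-ion")
        assert set(ion_ion.graph.edges) == {("i1", "i2")}

    def test_admission_is_monotone_in_cutoffs(self, mixed_corr):
        loose = sn.build_network(mixed_corr, r_cutoff=0.58, p_cutoff=0.05,
                                 mode="all")
        tight_r = sn.build_network(mixed_corr, r_cutoff=0.85, p_cutoff=0.05,
                                   mode="all")
        tight_p = sn.build_network(mixed_corr, r_cutoff=0.58, p_cutoff=1e-4,
                                   mode="all")
        assert set(tight_r.graph.edges) <= set(loose.graph.edges)
        assert set(tight_p.graph.edges) <= set(loose.graph.edges)

    def test_invalid_cutoffs_rejected(self, mixed_corr):
        with pytest.raises(ValidationError):
            sn.build_network(mixed_corr, r_cutoff=1.5)
        with pytest.raises(ValidationError):
            sn.build_network(mixed_corr, p_cutoff=0.0)


class TestNetworkStats:
    def test_paper_convention_average_degree(self):
        graph = nx.gnm_random_graph(19, 88, seed=1)
        assert min(dict(graph.degree()).values()) >= 1
        net = CorrelationNetwork(graph, "ion-ion", 0.58, 0.05)
        for u, v in graph.edges:
            graph.edges[u, v]["sign"] = "positive"
        stats = sn.network_stats(net)
        assert stats.average_degree_paper == pytest.approx(88 / 19)
        assert round(stats.average_degree_paper, 3) == 4.632
        assert stats.average_degree_standard == pytest.approx(
            2 * stats.average_degree_paper
        )

    def test_path_graph_metrics(self):
        net = make_network([("a", "b", "positive"), ("b", "c", "negative")])
        stats = sn.network_stats(net)
        assert stats.diameter == 2
        assert stats.average_path_length == pytest.approx(4 / 3)
        assert stats.n_positive == 1 and stats.n_negative == 1

    def test_cumulative_degree_distribution(self):
        net = make_network([("a", "b", "positive"), ("b", "c", "positive"),
                            ("b", "d", "positive")])
        stats = sn.network_stats(net)
        dist = stats.cumulative_degree_distribution
        assert dist[1] == 1.0
        values = [dist[k] for k in sorted(dist)]
        assert all(x >= y for x, y in zip(values, values[1:]))

    def test_empty_network_flagged(self):
        net = CorrelationNetwork(nx.Graph(), "ion-ion", 0.58, 0.05)
        stats = sn.network_stats(net)
        assert stats.n_nodes == 0 and stats.n_edges == 0
        assert not stats.path_metrics_defined


class TestCommunities:
    def test_two_triangles_have_modularity_half(self):
        net = make_network([
            ("a", "b", "positive"), ("b", "c", "positive"), ("a", "c", "positive"),
            ("x", "y", "positive"), ("y", "z", "positive"), ("x", "z", "positive"),
        ])
        communities, q = sn.detect_communities(net, seed=0)
        assert q == pytest.approx(0.5)
        assert len(set(communities.values())) == 2

    def test_complete_graph_single_community_is_zero(self):
        graph = nx.complete_graph(6)
        assert sn.modularity_score(graph, {n: 0 for n in graph}) == pytest.approx(0.0)

    def test_matches_networkx_modularity(self):
        rng = np.random.default_rng(2)
        for seed in range(20):
            graph = nx.gnp_random_graph(12, 0.3, seed=seed)
            if graph.number_of_edges() == 0:
                continue
            net = CorrelationNetwork(graph, "ion-ion", 0.58, 0.05)
            for u, v in graph.edges:
                graph.edges[u, v]["sign"] = "positive"
            communities, q = sn.detect_communities(net, seed=seed)
            groups = {}
            for node, comm in communities.items():
                groups.setdefault(comm, set()).add(node)
            q_ref = nx.community.modularity(graph, list(groups.values()))
            assert q == pytest.approx(q_ref, abs=1e-9)

    def test_deterministic_for_fixed_seed(self):
        graph = nx.gnp_random_graph(15, 0.25, seed=3)
        net = CorrelationNetwork(graph.copy(), "ion-ion", 0.58, 0.05)
        net2 = CorrelationNetwork(graph.copy(), "ion-ion", 0.58, 0.05)
        assert sn.detect_communities(net, seed=42) == sn.detect_communities(
            net2, seed=42
        )

    def test_edgeless_network_rejected(self):
        net = CorrelationNetwork(nx.Graph(), "ion-ion", 0.58, 0.05)
        with pytest.raises(ValidationError, match="at least one edge"):
            sn.detect_communities(net)


class TestGeneralists:
    def test_star_center_is_generalist(self):
        net = make_network([("hub", f"n{i}", "positive") for i in range(5)])
        ranked = sn.identify_generalists(net, top_k=1)
        assert ranked[0]["variable_id"] == "hub"
        assert ranked[0]["degree"] == 5

    def test_negative_fraction(self):
        edges = [("hub", f"n{i}", "negative") for i in range(8)]
        edges += [("hub", f"p{i}", "positive") for i in range(3)]
        ranked = sn.identify_generalists(make_network(edges), top_k=1)
        assert ranked[0]["degree"] == 11
        assert ranked[0]["negative_fraction"] == pytest.approx(8 / 11)
        assert round(100 * ranked[0]["negative_fraction"], 1) == 72.7

    def test_tie_broken_lexicographically(self):
        net = make_network([("b", "x", "positive"), ("a", "y", "positive")])
        ranked = sn.identify_generalists(net)
        assert [row["variable_id"] for row in ranked[:2]] == ["a", "b"]


class TestExport:
    @pytest.fixture
    def small_net(self):
        return make_network(
            [("a", "b", "positive"), ("b", "c", "negative")],
            categories={"a": "enzyme", "b": "ion", "c": "ion"},
        )

    @pytest.mark.parametrize("fmt", ["gexf", "graphml"])
    def test_round_trip_preserves_topology_and_attributes(self, small_net,
                                                          tmp_path, fmt):
        sn.detect_communities(small_net, seed=0)
        path = tmp_path / f"net.{fmt}"
        sn.export_network(small_net, path, format=fmt)
        back = sn.network.read_network(path, format=fmt)
        assert set(back.nodes) == set(small_net.graph.nodes)
        assert {frozenset(e) for e in back.edges} == {
            frozenset(e) for e in small_net.graph.edges
        }
        for u, v, data in back.edges(data=True):
            assert data["sign"] == small_net.graph.edges[u, v]["sign"]
            assert float(data["r"]) == pytest.approx(
                small_net.graph.edges[u, v]["r"]
            )
        for node, data in back.nodes(data=True):
            assert data["category"] == small_net.graph.nodes[node]["category"]

    def test_empty_network_exports_valid_file(self, tmp_path):
        net = CorrelationNetwork(nx.Graph(), "ion-ion", 0.58, 0.05)
        path = tmp_path / "empty.gexf"
        sn.export_network(net, path, format="gexf")
        assert nx.read_gexf(path).number_of_edges() == 0

    def test_sign_values_are_enumerated(self, small_net, tmp_path):
        path = tmp_path / "net.edgelist"
        sn.export_network(small_net, path, format="edgelist")
        signs = {line.split("\t")[3].strip()
                 for line in path.read_text().splitlines()[1:]}
        assert signs <= {"positive", "negative"}

    def test_unknown_format_rejected(self, small_net, tmp_path):
        with pytest.raises(ValidationError, match="unknown format"):
            sn.export_network(small_net, tmp_path / "x.bin", format="bin")
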