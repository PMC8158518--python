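"""Connectivity, differential connectivity, and topology profiling."""

from itertools import combinations

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import liponet as lp
from liponet.diffnet import DEFAULT_MEASURES, EXTRA_MEASURES
from liponet.network import mask_network


def network_from_weights(W):
    W = np.asarray(W, dtype=float)
    m = W.shape[0]
    R = W.copy()
    np.fill_diagonal(R, 1.0)
    P = (W != 0).astype(float)
    return mask_network(R, P, prob_threshold=0.5,
                        nodes=[f"v{i}" for i in range(m)])


def random_network(rng, m=10, p=0.3):
    W = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            if rng.random() < p:
                W[i, j] = W[j, i] = rng.uniform(-1, 1)
    return network_from_weights(W)


class TestConnectivity:
    def test_empty_network_is_all_zero(self):
        net = network_from_weights(np.zeros((5, 5)))
        assert (lp.connectivity(net) == 0).all()

    def test_single_negative_edge(self):
        W = np.zeros((4, 4))
        W[0, 1] = W[1, 0] = -0.4
        chi = lp.connectivity(network_from_weights(W))
        assert chi.tolist() == [0.4, 0.4, 0.0, 0.0]

    def test_handshake_identity_on_random_networks(self):
        """Summed node connectivity equals twice the total absolute edge
        weight, for arbitrary random networks."""
        rng = np.random.default_rng(1)
        for _ in range(30):
            net = random_network(rng)
            total = lp.connectivity(net).sum()
            brute = 2 * sum(
                abs(net.weights[i, j])
                for i, j in combinations(range(net.m), 2)
            )
            assert np.isclose(total, brute, atol=1e-12)


class TestDifferentialConnectivity:
    def test_z_scores_are_standardized(self):
        rng = np.random.default_rng(2)
        a, b = random_network(rng), random_network(rng)
        report = lp.differential_connectivity(a, b)
        assert abs(report.table["z"].mean()) < 1e-10
        assert abs(report.table["z"].std(ddof=1) - 1) < 1e-10

    def test_antisymmetric_in_the_two_networks(self):
        rng = np.random.default_rng(3)
        a, b = random_network(rng), random_network(rng)
        ab = lp.differential_connectivity(a, b).table
        ba = lp.differential_connectivity(b, a).table
        assert np.allclose(ab["delta"], -ba["delta"])
        assert np.allclose(ab["z"], -ba["z"])

    def test_single_outlier_node_is_selected(self):
        """Delta = (3, 0, ..., 0) over 21 nodes: direct z arithmetic says the
        outlier exceeds 2 and is the only selected node."""
        W = np.zeros((21, 21))
        W[0, 1] = W[1, 0] = 1.5
        a = network_from_weights(W)
        b = network_from_weights(np.zeros((21, 21)))
        report = lp.differential_connectivity(a, b).table
        delta = np.zeros(21)
        delta[:2] = 1.5
        z_direct = (delta - delta.mean()) / delta.std(ddof=1)
        assert np.allclose(report["delta"], delta)
        assert np.allclose(report["z"], z_direct)
        assert report["selected"].tolist() == (z_direct > 2).tolist()

    def test_identical_networks_degenerate_with_warning(self):
        net = random_network(np.random.default_rng(4))
        with pytest.warns(UserWarning, match="undefined"):
            report = lp.differential_connectivity(net, net)
        assert report.degenerate
        assert not report.table["selected"].any()

    def test_node_mismatch_is_an_error(self):
        a = random_network(np.random.default_rng(5), m=6)
        b = random_network(np.random.default_rng(6), m=7)
        with pytest.raises(ValueError, match="node set"):
            lp.differential_connectivity(a, b)


class TestTopologyProfile:
    def test_complete_graph_clustering(self):
        W = np.ones((4, 4)) * 0.5
        np.fill_diagonal(W, 0)
        prof = lp.topology_profile(network_from_weights(W))
        assert (prof.table["Clustering Coefficient"] == 1.0).all()
        assert (prof.table["Degree"] == 3).all()

    def test_path_graph_betweenness(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 0.5
        W[1, 2] = W[2, 1] = -0.5
        prof = lp.topology_profile(network_from_weights(W))
        assert prof.table.loc["v1", "Betweenness Centrality"] == 1.0
        assert prof.table.loc["v0", "Betweenness Centrality"] == 0.0

    def test_star_graph_degrees(self):
        W = np.zeros((5, 5))
        W[0, 1:] = W[1:, 0] = 0.3
        prof = lp.topology_profile(network_from_weights(W))
        assert prof.table.loc["v0", "Degree"] == 4
        assert (prof.table.loc["v1":, "Degree"] == 1).all()

    def test_matches_networkx_on_random_graphs(self):
        """Measures with a direct graph-library counterpart agree on 50
        random graphs (including disconnected ones)."""
        rng = np.random.default_rng(7)
        for _ in range(50):
            net = random_network(rng, m=8, p=0.25)
            prof = lp.topology_profile(net).table
            g = nx.Graph()
            g.add_nodes_from(net.nodes)
            for i, j in combinations(range(net.m), 2):
                if net.weights[i, j] != 0:
                    g.add_edge(net.nodes[i], net.nodes[j])
            assert np.allclose(prof["Degree"], [g.degree[v] for v in net.nodes])
            assert np.allclose(
                prof["Betweenness Centrality"],
                list(nx.betweenness_centrality(g).values()),
            )
            assert np.allclose(
                prof["Clustering Coefficient"], list(nx.clustering(g).values())
            )
            assert np.allclose(
                prof["Closeness Centrality"],
                list(nx.closeness_centrality(g, wf_improved=False).values()),
            )

    def test_stress_matches_enumeration_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            net = random_network(rng, m=7, p=0.35)
            prof = lp.topology_profile(net).table
            g = nx.Graph()
            g.add_nodes_from(net.nodes)
            for i, j in combinations(range(net.m), 2):
                if net.weights[i, j] != 0:
                    g.add_edge(net.nodes[i], net.nodes[j])
            stress = dict.fromkeys(g, 0)
            for s, t in combinations(g.nodes, 2):
                if nx.has_path(g, s, t):
                    for path in nx.all_shortest_paths(g, s, t):
                        for v in path[1:-1]:
                            stress[v] += 1
            assert np.allclose(prof["Stress"], [stress[v] for v in net.nodes])

    def test_isolated_node_conventions(self):
        W = np.zeros((4, 4))
        W[0, 1] = W[1, 0] = 0.5
        prof = lp.topology_profile(network_from_weights(W)).table
        iso = prof.loc["v3"]
        assert iso["Clustering Coefficient"] == 0
        assert iso["Eccentricity"] == 0
        assert iso["Closeness Centrality"] == 0
        assert not prof.isna().any().any()

    def test_extra_measures_available(self):
        net = random_network(np.random.default_rng(9))
        prof = lp.topology_profile(net, measures=DEFAULT_MEASURES + EXTRA_MEASURES)
        assert len(prof.measures) == 15


class TestNodeTopologyDistance:
    def test_identical_profiles_have_zero_distance(self):
        net = random_network(np.random.default_rng(10))
        prof = lp.topology_profile(net)
        out = lp.node_topology_distance(prof, prof)
        assert np.allclose(out["cosine_distance"], 0, atol=1e-12)

    def test_orthogonal_vectors_have_distance_one(self):
        import pandas as pd

        from liponet.diffnet import TopologyProfile

        a = TopologyProfile(pd.DataFrame([[1.0, 0.0], [1.0, 1.0]],
                                         columns=["m1", "m2"], index=["u", "v"]))
        b = TopologyProfile(pd.DataFrame([[0.0, 1.0], [1.0, 1.0]],
                                         columns=["m1", "m2"], index=["u", "v"]))
        out = lp.node_topology_distance(a, b)
        assert out.loc["u", "cosine_distance"] == pytest.approx(1.0)

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 10_000))
    def test_distance_bounded_for_nonnegative_profiles(self, seed):
        import pandas as pd

        from liponet.diffnet import TopologyProfile

        rng = np.random.default_rng(seed)
        a = TopologyProfile(pd.DataFrame(rng.uniform(0, 5, (6, 4))))
        b = TopologyProfile(pd.DataFrame(rng.uniform(0, 5, (6, 4))))
        d = lp.node_topology_distance(a, b)["cosine_distance"]
        assert ((d >= -1e-12) & (d <= 1 + 1e-12)).all()


class TestTopologyPca:
    def test_identical_conditions_coincide_in_score_space(self):
        net = random_network(np.random.default_rng(11))
        prof = lp.topology_profile(net, condition="x")
        model, meta = lp.topology_pca({"a": prof, "b": prof})
        half = len(meta) // 2
        assert np.allclose(model.scores[:half], model.scores[half:], atol=1e-10)

    def test_score_matrix_shape(self):
        rng = np.random.default_rng(12)
        a = lp.topology_profile(random_network(rng, m=21))
        b = lp.topology_profile(random_network(rng, m=21))
        model, meta = lp.topology_pca({"a": a, "b": b})
        assert model.scores.shape[0] == 42
        assert model.scores.shape[1] <= 11

    def test_heavier_rewiring_moves_nodes_further(self):
        """Mean paired score-space distance grows with the fraction of
        rewired edges (three levels)."""
        rng = np.random.default_rng(13)
        base = random_network(rng, m=21, p=0.25)
        mean_dist = []
        for n_rewire in (2, 8, 20):
            W = base.weights.copy()
            edges = np.argwhere(np.triu(W, 1) != 0)
            drop = edges[rng.choice(len(edges), min(n_rewire, len(edges)),
                                    replace=False)]
            for i, j in drop:
                W[i, j] = W[j, i] = 0.0
                a, b = rng.choice(21, 2, replace=False)
                W[a, b] = W[b, a] = rng.uniform(0.2, 1.0)
            other = network_from_weights(W)
            pa = lp.topology_profile(base)
            pb = lp.topology_profile(other)
            model, meta = lp.topology_pca({"a": pa, "b": pb})
            half = len(meta) // 2
            mean_dist.append(
                np.linalg.norm(model.scores[:half] - model.scores[half:], axis=1).mean()
            )
        assert mean_dist[0] < mean_dist[2]
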