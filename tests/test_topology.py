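"""Centrality, keystone and core-network rules against brute-force oracles."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

import seepnet as sp

from conftest import random_graph


def brute_force_betweenness(g: nx.Graph) -> dict:
    """Unnormalized betweenness by explicit shortest-path enumeration.

    For every unordered pair, all shortest paths are enumerated by
    depth-first search constrained to BFS distance layers, and each interior
    node is credited its fraction of the pair's paths.
    """
    nodes = list(g.nodes)
    btw = {v: 0.0 for v in nodes}
    for i, s in enumerate(nodes):
        dist = nx.single_source_shortest_path_length(g, s)
        for t in nodes[i + 1:]:
            if t not in dist:
                continue
            paths = []

            def extend(path):
                v = path[-1]
                if v == t:
                    paths.append(path)
                    return
                for u in g.neighbors(v):
                    if u in dist and dist[u] == dist[v] + 1 and dist[u] <= dist[t]:
                        extend(path + [u])

            extend([s])
            for path in paths:
                for v in path[1:-1]:
                    btw[v] += 1.0 / len(paths)
    return btw


class TestCentralities:
    def test_complete_graph(self):
        table = sp.compute_centralities(sp.make_fixture_graph("complete", 5))
        assert (table["degree"] == 4).all()
        assert (table["betweenness"] == 0.0).all()
        assert (table["mean_abs_weight"] == 1.0).all()

    def test_path_three_nodes(self):
        table = sp.compute_centralities(sp.make_fixture_graph("path", 3))
        assert list(table["degree"]) == [1, 2, 1]
        assert list(table["betweenness"]) == [0.0, 1.0, 0.0]

    def test_barbell_bridge_has_maximal_betweenness(self):
        net = sp.make_fixture_graph("barbell", 10)
        table = sp.compute_centralities(net)
        bridge = table["betweenness"].nlargest(2).index
        # the two clique nodes carrying the bridge edge dominate
        degrees = table.loc[bridge, "degree"]
        assert (degrees == 5).all()
        assert table["betweenness"].drop(bridge).max() < table.loc[bridge, "betweenness"].min()

    @pytest.mark.parametrize("trial", range(10))
    def test_betweenness_matches_brute_force(self, trial):
        g = random_graph(int(np.random.default_rng(trial).integers(4, 13)), 0.35,
                         seed=trial)
        net = sp.InteractionNetwork(g)
        nx.set_edge_attributes(g, 1.0, "weight")
        table = sp.compute_centralities(net)
        oracle = brute_force_betweenness(g)
        for v in g.nodes:
            assert table.loc[v, "betweenness"] == pytest.approx(oracle[v])

    def test_degree_sum_is_twice_edge_count(self):
        net = sp.make_fixture_graph("erdos_renyi", 30, p_edge=0.2, seed=5)
        table = sp.compute_centralities(net)
        assert table["degree"].sum() == 2 * net.n_edges

    def test_mean_abs_weight_uses_absolute_values(self):
        g = nx.Graph()
        g.add_edge("a", "b", weight=-2.0)
        g.add_edge("a", "c", weight=1.0)
        table = sp.compute_centralities(sp.InteractionNetwork(g))
        assert table.loc["a", "mean_abs_weight"] == pytest.approx(1.5)


class TestKeystones:
    def test_all_tied_metrics_select_everything(self):
        table = pd.DataFrame({"degree": [3, 3, 3], "betweenness": [1.0, 1.0, 1.0],
                              "mean_abs_weight": [1, 1, 1],
                              "domain": ["bacteria"] * 3},
                             index=["a", "b", "c"])
        report = sp.keystone_nodes(table, 0.8)
        assert set(report.keystone_ids) == {"a", "b", "c"}

    def test_barbell_bridge_endpoints_are_keystones(self):
        net = sp.make_fixture_graph("barbell", 10)
        table = sp.compute_centralities(net)
        report = sp.keystone_nodes(table, 0.8)
        top2 = set(table["betweenness"].nlargest(2).index)
        assert top2 <= set(report.keystone_ids)

    def test_thresholds_are_linear_interpolation_quantiles(self):
        rng = np.random.default_rng(0)
        table = pd.DataFrame({
            "degree": rng.integers(1, 20, 25),
            "betweenness": rng.random(25) * 10,
            "mean_abs_weight": rng.random(25),
            "domain": ["bacteria"] * 25,
        }, index=[f"t{i}" for i in range(25)])
        report = sp.keystone_nodes(table, 0.8)
        assert report.degree_threshold == pytest.approx(np.quantile(table["degree"], 0.8))
        assert report.betweenness_threshold == pytest.approx(
            np.quantile(table["betweenness"], 0.8))


class TestCoreNetwork:
    def test_star_collapses_to_empty_core(self):
        core = sp.core_network(sp.make_fixture_graph("star", 10), 0.5, min_edges=3)
        assert core.n_nodes == 0
        assert core.provenance["empty"]

    def test_complete_graph_unchanged(self):
        core = sp.core_network(sp.make_fixture_graph("complete", 6), 0.5, min_edges=3)
        assert core.n_nodes == 6
        assert core.n_edges == 15

    def test_zero_percentile_equals_min_edge_filter(self):
        net = sp.make_fixture_graph("erdos_renyi", 25, p_edge=0.15, seed=11)
        core = sp.core_network(net, 0.0, min_edges=3)
        # single min-edge pass on the (here: whole) induced graph, then
        # drop whatever that pass isolated
        sub = net.graph.copy()
        sub.remove_nodes_from([v for v, d in net.graph.degree if d < 3])
        sub.remove_nodes_from([v for v, d in sub.degree if d == 0])
        assert set(core.graph.nodes) == set(sub.nodes)

    def test_core_is_subgraph_and_monotone_in_min_edges(self):
        net = sp.make_fixture_graph("erdos_renyi", 30, p_edge=0.25, seed=12)
        prev = None
        for min_edges in (1, 2, 3, 4):
            core = sp.core_network(net, 0.3, min_edges=min_edges)
            nodes = set(core.graph.nodes)
            assert nodes <= set(net.graph.nodes)
            for u, v in core.graph.edges:
                assert net.graph.has_edge(u, v)
            if prev is not None:
                assert nodes <= prev
            prev = nodes


class TestDomainComparison:
    def _table(self, a_vals, b_vals):
        rows = [{"degree": v, "betweenness": v, "mean_abs_weight": v,
                 "domain": "bacteria"} for v in a_vals]
        rows += [{"degree": v, "betweenness": v, "mean_abs_weight": v,
                  "domain": "fungus"} for v in b_vals]
        return pd.DataFrame(rows, index=[f"t{i}" for i in range(len(rows))])

    def test_identical_groups_not_significant(self):
        table = self._table([1, 2, 3, 4, 5], [1, 2, 3, 4, 5])
        res = sp.compare_domain_metric(table, "degree", "bacteria", "fungus")
        assert res.p_value > 0.9
        assert res.median_a == res.median_b

    def test_large_shift_detected(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, 30)
        b = rng.normal(10, 1, 30)
        res = sp.compare_domain_metric(self._table(a, b), "mean_abs_weight",
                                       "bacteria", "fungus")
        assert res.p_value < 1e-3
        assert res.top20_share_b == 1.0

    def test_inflated_fungal_weights_rank_higher(self):
        # planted effect: fungal couplings stronger than bacterial ones
        rng = np.random.default_rng(2)
        g = nx.gnp_random_graph(40, 0.2, seed=3)
        g = nx.relabel_nodes(g, {i: f"t{i}" for i in range(40)})
        for u, v in g.edges:
            fungal = u in [f"t{i}" for i in range(10)] or v in [f"t{i}" for i in range(10)]
            g[u][v]["weight"] = rng.normal(0, 2.5 if fungal else 0.8)
        for i in range(40):
            g.nodes[f"t{i}"]["domain"] = "fungus" if i < 10 else "bacteria"
        res = sp.compare_domain_metric(
            sp.compute_centralities(sp.InteractionNetwork(g)),
            "mean_abs_weight", "fungus", "bacteria")
        assert res.median_a > res.median_b
        assert res.p_value < 0.01

    def test_missing_domain_rejected(self):
        table = self._table([1, 2, 3], [4, 5, 6])
        with pytest.raises(ValueError):
            sp.compare_domain_metric(table, "degree", "bacteria", "archaea")
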