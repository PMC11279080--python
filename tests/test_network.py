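"""Co-occurrence networks: correlations, thresholds, modules, topology, roles."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from oracles import (
    avg_path_bf,
    betweenness_bf,
    bh_bf,
    closeness_bf,
    clustering_bf,
    modularity_bf,
    pi_bf,
    random_graph,
    spearman_bf,
    zi_bf,
)
from poolcomm import tables
from poolcomm.network import (
    adjust_p_matrix,
    bh_adjust,
    build_network,
    classify_roles,
    correlation_matrices,
    detect_modules,
    modularity,
    site_network,
    topology_summary,
    zi_pi,
)


def _table(rows, columns=None):
    df = pd.DataFrame(
        rows, index=[f"m{i}" for i in range(len(rows))],
        columns=columns or [f"t{j}" for j in range(len(rows[0]))],
    )
    return tables.CountTable(df)


class TestCorrelationMatrices:
    def test_diagonal_excluded(self):
        table = _table([[1, 2], [2, 3], [3, 4], [4, 5], [5, 6]])
        r, p = correlation_matrices(table)
        assert np.isnan(r.iloc[0, 0]) and np.isnan(p.iloc[1, 1])

    def test_monotone_map_gives_unit_correlation(self):
        base = [1, 5, 2, 8, 3]
        mapped = [x**2 + 1 for x in base]  # strictly increasing on positives
        table = _table(list(zip(base, mapped)))
        r, _ = correlation_matrices(table)
        assert r.iloc[0, 1] == pytest.approx(1.0)

    def test_hand_entered_vectors_match_rank_oracle(self):
        x, y = (3, 1, 4, 1, 5), (2, 7, 1, 8, 2)
        table = _table(list(zip(x, y)))
        r, p = correlation_matrices(table)
        assert r.iloc[0, 1] == pytest.approx(spearman_bf(x, y), abs=1e-12)
        expected = stats.spearmanr(x, y)
        assert r.iloc[0, 1] == pytest.approx(expected.statistic, abs=1e-12)
        assert p.iloc[0, 1] == pytest.approx(expected.pvalue, abs=1e-10)

    def test_constant_taxon_undefined(self):
        table = _table([[1, 5], [2, 5], [3, 5], [4, 5], [5, 5]])
        r, p = correlation_matrices(table)
        assert np.isnan(r.iloc[0, 1]) and np.isnan(p.iloc[0, 1])

    def test_matches_scipy_on_random_table(self, rng):
        data = rng.integers(0, 100, size=(11, 6))
        table = _table(data.tolist())
        r, _ = correlation_matrices(table)
        expected = stats.spearmanr(data).statistic
        mask = ~np.eye(6, dtype=bool)
        assert np.allclose(r.to_numpy()[mask], expected[mask], atol=1e-12)


class TestBhAdjust:
    def test_worked_example_all_collapse(self):
        out = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_all_ones(self):
        assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_single_p_unchanged(self):
        assert bh_adjust([0.3])[0] == pytest.approx(0.3)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    def test_matches_stepup_definition_oracle(self, rng):
        for _ in range(20):
            p = rng.random(rng.integers(1, 15))
            assert np.allclose(bh_adjust(p), bh_bf(p.tolist()), atol=1e-12)

    def test_matrix_adjustment_symmetric_over_upper_triangle(self, rng):
        mat = rng.random((5, 5))
        mat = (mat + mat.T) / 2
        np.fill_diagonal(mat, np.nan)
        p = pd.DataFrame(mat, index=list("abcde"), columns=list("abcde"))
        adj = adjust_p_matrix(p)
        assert np.allclose(adj.to_numpy(), adj.to_numpy().T, equal_nan=True)
        iu = np.triu_indices(5, 1)
        assert np.allclose(
            adj.to_numpy()[iu], bh_bf(mat[iu].tolist()), atol=1e-12
        )


class TestBuildNetwork:
    def _mats(self, r01, p01):
        ids = ["a", "b"]
        r = pd.DataFrame([[np.nan, r01], [r01, np.nan]], index=ids, columns=ids)
        p = pd.DataFrame([[np.nan, p01], [p01, np.nan]], index=ids, columns=ids)
        return r, p

    def test_r_exactly_at_threshold_is_no_edge(self):
        graph = build_network(*self._mats(0.7, 0.0001))
        assert graph.number_of_edges() == 0

    def test_strong_negative_correlation_is_negative_edge(self):
        graph = build_network(*self._mats(-0.9, 0.001))
        assert graph.number_of_edges() == 1
        assert graph.edges["a", "b"]["sign"] == "-"

    def test_p_at_threshold_is_no_edge(self):
        graph = build_network(*self._mats(0.9, 0.01))
        assert graph.number_of_edges() == 0

    def test_isolated_taxa_excluded(self):
        ids = list("abc")
        r = pd.DataFrame(np.nan, index=ids, columns=ids)
        p = pd.DataFrame(np.nan, index=ids, columns=ids)
        r.loc["a", "b"] = r.loc["b", "a"] = 0.95
        p.loc["a", "b"] = p.loc["b", "a"] = 0.001
        graph = build_network(r, p)
        assert set(graph.nodes) == {"a", "b"}

    def test_empty_after_threshold_gives_zero_summary(self):
        graph = build_network(*self._mats(0.2, 0.9))
        summary = topology_summary(graph, {})
        assert summary.degenerate
        assert summary.n_nodes == summary.n_edges == 0
        assert summary.average_degree == 0.0


class TestModules:
    def _two_cliques(self, size=5):
        g = nx.Graph()
        for offset in (0, size):
            for a, b in itertools.combinations(range(offset, offset + size), 2):
                g.add_edge(a, b)
        return g

    def test_disjoint_cliques_recovered_exactly(self):
        g = self._two_cliques()
        partition, q = detect_modules(g, seed=0)
        assert len(set(partition.values())) == 2
        assert len({partition[n] for n in range(5)}) == 1
        assert len({partition[n] for n in range(5, 10)}) == 1
        assert q > 0.4

    def test_complete_graph_single_module(self):
        g = nx.complete_graph(6)
        partition, _ = detect_modules(g, seed=0)
        assert len(set(partition.values())) == 1

    def test_twin_triangles_modularity_half(self):
        g = nx.Graph([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])
        partition = {0: 0, 1: 0, 2: 0, 3: 1, 4: 1, 5: 1}
        assert modularity(g, partition) == pytest.approx(0.5)

    def test_single_module_zero(self):
        g = nx.complete_graph(4)
        assert modularity(g, {n: 0 for n in g.nodes}) == pytest.approx(0.0)

    def test_matches_bruteforce_on_random_partitions(self, rng):
        for _ in range(10):
            nodes, edges = random_graph(rng, 10, 0.35)
            if not edges:
                continue
            g = nx.Graph(edges)
            g.add_nodes_from(nodes)
            partition = {n: int(rng.integers(0, 3)) for n in nodes}
            assert modularity(g, partition) == pytest.approx(
                modularity_bf(edges, partition), abs=1e-12
            )
            assert modularity(g, partition) == pytest.approx(
                nx.community.modularity(
                    g, [ [n for n in nodes if partition[n] == s]
                         for s in set(partition.values()) ]
                ),
                abs=1e-12,
            )

    def test_uncovered_partition_rejected(self):
        g = nx.complete_graph(3)
        with pytest.raises(ValueError, match="cover"):
            modularity(g, {0: 0, 1: 0})


class TestTopologySummary:
    def test_triangle_closed_forms(self):
        g = nx.complete_graph(3)
        s = topology_summary(g, {n: 0 for n in g.nodes})
        assert s.average_degree == pytest.approx(2.0)
        assert s.avg_clustering == pytest.approx(1.0)
        assert s.avg_path_distance == pytest.approx(1.0)

    def test_path_graph_closed_forms(self):
        g = nx.path_graph(3)
        s = topology_summary(g, {n: 0 for n in g.nodes})
        assert s.avg_clustering == pytest.approx(0.0)
        assert s.avg_path_distance == pytest.approx(4 / 3)
        assert s.avg_betweenness == pytest.approx(1 / 3)

    def test_module_size_threshold_strict(self):
        g = nx.complete_graph(5)
        s5 = topology_summary(g, {n: 0 for n in g.nodes})
        assert s5.n_modules_gt5 == 0  # "more than 5 nodes" is strict
        g6 = nx.complete_graph(6)
        s6 = topology_summary(g6, {n: 0 for n in g6.nodes})
        assert s6.n_modules_gt5 == 1

    def test_edge_sign_percentages(self):
        g = nx.Graph()
        g.add_edge("a", "b", sign="+")
        g.add_edge("b", "c", sign="-")
        g.add_edge("c", "d", sign="-")
        g.add_edge("d", "a", sign="-")
        s = topology_summary(g, {n: 0 for n in g.nodes})
        assert s.pct_positive == pytest.approx(25.0)
        assert s.pct_negative == pytest.approx(75.0)
        assert s.pct_positive + s.pct_negative == pytest.approx(100.0)

    def test_matches_bruteforce_on_random_graphs(self, rng):
        for _ in range(8):
            nodes, edges = random_graph(rng, 9, 0.3)
            if not edges:
                continue
            g = nx.Graph(edges)
            g.add_nodes_from(nodes)
            g.remove_nodes_from([n for n in nodes if g.degree[n] == 0])
            live = list(g.nodes)
            live_edges = list(g.edges)
            s = topology_summary(g, {n: 0 for n in live})
            assert s.avg_clustering == pytest.approx(clustering_bf(live, live_edges), abs=1e-10)
            assert s.avg_path_distance == pytest.approx(avg_path_bf(live, live_edges), abs=1e-10)
            bf_b = betweenness_bf(live, live_edges)
            assert s.avg_betweenness == pytest.approx(
                np.mean([bf_b[n] for n in live]), abs=1e-10
            )
            bf_c = closeness_bf(live, live_edges)
            assert s.avg_closeness == pytest.approx(
                np.mean([bf_c[n] for n in live]), abs=1e-10
            )


class TestZiPi:
    def test_all_links_internal_gives_zero_pi(self):
        g = nx.complete_graph(4)
        frame = zi_pi(g, {n: 0 for n in g.nodes})
        assert (frame["Pi"] == 0.0).all()

    def test_even_split_across_two_modules(self):
        g = nx.star_graph(4)  # hub 0 with leaves 1-4
        partition = {0: 0, 1: 0, 2: 0, 3: 1, 4: 1}
        frame = zi_pi(g, partition)
        assert frame.loc[0, "Pi"] == pytest.approx(0.5)  # 1 - (0.5^2 + 0.5^2)

    def test_uniform_within_module_degree_gives_zero_zi(self):
        g = nx.complete_graph(5)
        frame = zi_pi(g, {n: 0 for n in g.nodes})
        assert (frame["Zi"] == 0.0).all()

    def test_matches_bruteforce(self, rng):
        for _ in range(10):
            nodes, edges = random_graph(rng, 10, 0.4)
            if not edges:
                continue
            g = nx.Graph(edges)
            g.remove_nodes_from([n for n in nodes if n not in g])
            live = list(g.nodes)
            partition = {n: int(rng.integers(0, 3)) for n in live}
            frame = zi_pi(g, partition)
            bz = zi_bf(live, list(g.edges), partition)
            bp = pi_bf(live, list(g.edges), partition)
            for n in live:
                assert frame.loc[n, "Zi"] == pytest.approx(bz[n], abs=1e-10)
                assert frame.loc[n, "Pi"] == pytest.approx(bp[n], abs=1e-10)


class TestClassifyRoles:
    @pytest.mark.parametrize(
        "zi,pi,role",
        [
            (3.0, 0.7, "network_hub"),
            (3.0, 0.1, "module_hub"),
            (0.0, 0.7, "connector"),
            (0.0, 0.0, "peripheral"),
            (2.5, 0.62, "peripheral"),   # both boundaries fall non-hub side
            (2.5, 0.7, "connector"),
            (2.51, 0.62, "module_hub"),
            (2.51, 0.63, "network_hub"),
        ],
    )
    def test_role_assignment(self, zi, pi, role):
        assert classify_roles(zi, pi) == role

    def test_exactly_one_role_everywhere(self):
        for zi in np.linspace(-3, 5, 17):
            for pi in np.linspace(0, 1, 11):
                assert classify_roles(zi, pi) in {
                    "network_hub", "module_hub", "connector", "peripheral"
                }

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            classify_roles(float("nan"), 0.5)


class TestSiteNetworkIntegration:
    def test_every_edge_satisfies_thresholds(self, default_bundle, rarefied_16s):
        frame = default_bundle["frame"]
        site_rows = frame.index[frame["site"] == "Site 1"]
        filtered = tables.prevalence_abundance_filter(
            tables.CountTable(rarefied_16s.data.loc[site_rows])
        )
        graph, partition, summary, roles = site_network(filtered, seed=0)
        for _, _, d in graph.edges(data=True):
            assert abs(d["spearman_r"]) > 0.7
            assert d["p_adjusted"] < 0.01
            assert d["sign"] == ("+" if d["spearman_r"] > 0 else "-")
        assert summary.n_nodes == graph.number_of_nodes()
        assert set(roles.index) == set(graph.nodes)

    def test_month_removal_smoke(self, default_bundle, rarefied_16s):
        # dropping one month must not break any structural invariant
        frame = default_bundle["frame"]
        site_rows = frame.index[frame["site"] == "Site 1"][:-1]
        filtered = tables.prevalence_abundance_filter(
            tables.CountTable(rarefied_16s.data.loc[site_rows])
        )
        graph, partition, summary, roles = site_network(filtered, seed=0)
        assert summary.pct_positive + summary.pct_negative in (0.0, pytest.approx(100.0))
        assert set(partition) == set(graph.nodes)
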