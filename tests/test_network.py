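import itertools
import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import special, stats

import rhizonet as rz
from rhizonet.diversity import NormalizedTable
from rhizonet.io import Network, TableError
from rhizonet.network import _ks_distance

from conftest import best_partition_modularity, spearman_bruteforce


def _nt(matrix):
    m = np.asarray(matrix, dtype=float)
    return NormalizedTable(
        [f"t{i}" for i in range(m.shape[0])],
        [f"s{j}" for j in range(m.shape[1])],
        m,
        np.ones(m.shape[1]),
        "css",
    )


class TestPairwiseAssociations:
    def test_monotone_pair_perfect_rho(self):
        nt = _nt([[1, 2, 3, 4, 5], [2, 4, 9, 16, 30]])
        assoc = rz.pairwise_associations(nt, "spearman")
        assert assoc["coefficient"].iloc[0] == pytest.approx(1.0)
        assert assoc["p"].iloc[0] < 1e-12

    def test_rank_formula_direct_evaluation(self):
        # the pattern (1,2,3) vs (3,1,2): rho = 1 - 6*6/(3*8) = -0.5;
        # duplicating the pattern preserves the rank correlation
        nt = _nt([[1, 2, 3, 1, 2, 3], [3, 1, 2, 3, 1, 2]])
        assoc = rz.pairwise_associations(nt, "spearman")
        assert assoc["coefficient"].iloc[0] == pytest.approx(-0.5)

    def test_vectorized_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(17)
        values = rng.random(size=(10, 8)) * 100
        nt = _nt(values)
        assoc = rz.pairwise_associations(nt, "spearman")
        oracle = spearman_bruteforce(values)
        for r in assoc.itertuples():
            i = int(r.taxon_i[1:])
            j = int(r.taxon_j[1:])
            assert r.coefficient == pytest.approx(oracle[i, j], abs=1e-12)

    def test_p_values_match_scipy(self):
        rng = np.random.default_rng(2)
        values = rng.normal(size=(4, 12))
        assoc = rz.pairwise_associations(_nt(values), "pearson")
        for r in assoc.itertuples():
            i, j = int(r.taxon_i[1:]), int(r.taxon_j[1:])
            ref = stats.pearsonr(values[i], values[j])
            assert r.coefficient == pytest.approx(ref.statistic, abs=1e-12)
            assert r.p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_zero_variance_taxon_excluded(self, caplog):
        import logging

        nt = _nt([[1, 1, 1, 1], [1, 2, 3, 4], [4, 3, 2, 1]])
        with caplog.at_level(logging.WARNING):
            assoc = rz.pairwise_associations(nt)
        assert len(assoc) == 1  # only the t1-t2 pair is testable
        assert "zero-variance" in caplog.text

    def test_q_at_least_p(self):
        rng = np.random.default_rng(5)
        assoc = rz.pairwise_associations(_nt(rng.random(size=(8, 10))))
        assert (assoc["q"] >= assoc["p"] - 1e-15).all()


class TestBhFdr:
    def test_hand_stepped_example(self):
        np.testing.assert_allclose(
            rz.bh_fdr([0.005, 0.01, 0.03, 0.04]), [0.02, 0.02, 0.04, 0.04]
        )

    def test_single_and_tied_inputs(self):
        assert rz.bh_fdr([0.37])[0] == pytest.approx(0.37)
        np.testing.assert_allclose(rz.bh_fdr([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_matches_statsmodels_and_dominates_p(self, ps):
        from statsmodels.stats.multitest import multipletests

        q = rz.bh_fdr(ps)
        ref = multipletests(ps, method="fdr_bh")[1]
        np.testing.assert_allclose(q, ref, atol=1e-12)
        assert (q >= np.asarray(ps) - 1e-15).all()


class TestBuildNetwork:
    @staticmethod
    def _assoc(rows):
        return pd.DataFrame(
            rows, columns=["taxon_i", "taxon_j", "method", "coefficient", "p", "q", "sign"]
        )

    def test_thresholds_and_isolated_nodes(self):
        assoc = self._assoc(
            [
                ("a", "b", "spearman", 0.9, 1e-5, 0.01, 1),
                ("a", "c", "spearman", 0.61, 1e-3, 0.2, 1),   # q too high
                ("b", "c", "spearman", 0.5, 1e-4, 0.01, 1),   # |rho| too low
                ("c", "d", "spearman", -0.8, 1e-6, 0.001, -1),
            ]
        )
        net = rz.build_network(assoc)
        assert set(net.graph.nodes) == {"a", "b", "c", "d"}
        assert net.edge_count == 2
        assert net.graph.edges[("c", "d")]["sign"] == -1

    def test_empty_when_nothing_passes(self):
        net = rz.build_network(
            self._assoc([("a", "b", "spearman", 0.3, 0.5, 0.9, 1)])
        )
        assert net.node_count == 0 and net.edge_count == 0

    def test_invariant_to_association_order(self):
        rows = [
            ("a", "b", "spearman", 0.9, 1e-5, 0.01, 1),
            ("c", "d", "spearman", 0.7, 1e-4, 0.02, 1),
            ("b", "c", "spearman", -0.65, 1e-3, 0.04, -1),
        ]
        a = rz.build_network(self._assoc(rows))
        b = rz.build_network(self._assoc(rows[::-1]))
        assert nx.utils.graphs_equal(a.graph, b.graph)


class TestTopologyMetrics:
    def test_regular_graph_centralization_zero(self):
        assert rz.centralization_degree(rz.fixture_graph("two_triangles")) == 0.0

    def test_star_and_path_centralization(self):
        assert rz.centralization_degree(rz.fixture_graph("star4")) == pytest.approx(1.0)
        assert rz.centralization_degree(rz.fixture_graph("path_3")) == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "name", ["two_triangles", "three_triangles", "complete4", "star4", "path_5"]
    )
    def test_walktrap_matches_exhaustive_modularity_search(self, name):
        net = rz.fixture_graph(name)
        q_walktrap = rz.modularity(net, rz.walktrap_communities(net))
        assert q_walktrap == pytest.approx(best_partition_modularity(net), abs=1e-9)

    def test_walktrap_matches_exhaustive_on_connected_bridge_graph(self):
        # two triangles joined by a single bridge edge
        g = nx.Graph([("a", "b"), ("b", "c"), ("a", "c"),
                      ("c", "d"), ("d", "e"), ("e", "f"), ("d", "f")])
        net = Network(g)
        q = rz.modularity(net, rz.walktrap_communities(net))
        assert q == pytest.approx(best_partition_modularity(net), abs=1e-9)

    def test_components_never_share_communities(self):
        net = rz.fixture_graph("three_triangles")
        part = rz.walktrap_communities(net)
        for comp in nx.connected_components(net.graph):
            labels = {part[v] for v in comp}
            others = {part[v] for v in net.graph.nodes if v not in comp}
            assert not (labels & others)

    def test_clique_partition_modularity_closed_form(self):
        # c disjoint equal cliques under the clique partition: Q = 1 - 1/c
        for name, c in [("two_triangles", 2), ("three_triangles", 3)]:
            net = rz.fixture_graph(name)
            part = rz.walktrap_communities(net)
            assert rz.modularity(net, part) == pytest.approx(1 - 1 / c)

    def test_all_in_one_partition_modularity_zero(self):
        for name in ["two_triangles", "complete4", "star4", "path_5"]:
            net = rz.fixture_graph(name)
            part = {v: 0 for v in net.graph.nodes}
            assert rz.modularity(net, part) == pytest.approx(0.0, abs=1e-12)

    def test_hub_scores_regular_and_disconnected(self):
        scores = rz.hub_scores(rz.fixture_graph("two_triangles"))
        np.testing.assert_allclose(list(scores.values()), 1.0)
        assert rz.hub_count(scores) == 6

    def test_hub_scores_star(self):
        scores = rz.hub_scores(rz.fixture_graph("star4"))
        assert scores["n1"] == pytest.approx(1.0)
        for leaf in ("n2", "n3", "n4"):
            assert scores[leaf] == pytest.approx(1 / math.sqrt(3), abs=1e-9)
        assert rz.hub_count(scores) == 4

    def test_hub_scores_match_igraph_on_connected_graph(self):
        import igraph as ig

        g = nx.gnm_random_graph(12, 24, seed=5)
        net = Network(nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes}))
        mine = rz.hub_scores(net)
        nodes = sorted(net.graph.nodes)
        gi = ig.Graph()
        gi.add_vertices(nodes)
        gi.add_edges(list(net.graph.edges))
        ref = gi.hub_score(scale=True)
        for v, r in zip(nodes, ref):
            assert mine[v] == pytest.approx(r, abs=1e-6)

    def test_hub_scores_invariant_to_sign_and_relabeling(self):
        net_pos = rz.Network.from_edges([("a", "b", 0.9, 0, 0), ("b", "c", 0.8, 0, 0)])
        net_neg = rz.Network.from_edges([("a", "b", -0.9, 0, 0), ("b", "c", -0.8, 0, 0)])
        assert rz.hub_scores(net_pos) == rz.hub_scores(net_neg)
        relabeled = rz.Network(nx.relabel_nodes(net_pos.graph, {"a": "z"}))
        assert rz.hub_scores(relabeled)["z"] == rz.hub_scores(net_pos)["a"]


class TestPowerLawFit:
    def test_constant_degrees_undefined(self):
        fit = rz.power_law_fit([2, 2, 2, 2])
        assert not fit.defined and math.isnan(fit.ks_stat)

    def test_ks_statistic_matches_bruteforce_scan(self):
        rng = np.random.default_rng(0)
        degrees = rng.integers(1, 20, size=40)
        fit = rz.power_law_fit(degrees)
        tail = np.asarray([d for d in degrees if d >= fit.xmin])
        z = special.zeta(fit.alpha, fit.xmin)
        worst = 0.0
        for x in range(fit.xmin, tail.max() + 1):
            fitted = 1.0 - special.zeta(fit.alpha, x + 1.0) / z
            ecdf = (tail <= x).mean()
            worst = max(worst, abs(ecdf - fitted))
        assert fit.ks_stat == pytest.approx(worst, abs=1e-12)

    def test_alpha_recovery_single_draw(self):
        xs = np.arange(1, 100001)
        pmf = xs ** (-2.5) / special.zeta(2.5, 1)
        cdf = np.cumsum(pmf)
        u = np.random.default_rng(1).random(1000) * cdf[-1]
        sample = np.searchsorted(cdf, u) + 1
        fit = rz.power_law_fit(sample)
        assert fit.defined and abs(fit.alpha - 2.5) <= 0.3


class TestSummarizeTopology:
    def test_two_triangles_matches_printed_row(self):
        ts = rz.summarize_topology(rz.fixture_graph("two_triangles"))
        assert ts.centralization_degree == 0.0
        assert ts.cluster_count == 2
        assert ts.connectance == pytest.approx(0.40)
        assert ts.edge_count == 6
        assert ts.giant_component_size == 3
        assert ts.hub_count == 6
        assert math.isnan(ts.ks_stat)
        assert ts.mean_degree == pytest.approx(2.00)
        assert ts.modularity == pytest.approx(0.50)
        assert ts.node_count == 6

    def test_degree_identities_hold_for_every_printed_row(self):
        from rhizonet.reference import load_topologies

        for method in ("spearman", "pearson"):
            table = load_topologies(method)
            for _, row in table.iterrows():
                n, e = row["node_count"], row["edge_count"]
                # printed values are rounded to 2 decimals (half away from
                # zero), so agreement is to half a unit in the last place
                assert 2 * e / (n * (n - 1)) == pytest.approx(
                    row["connectance"], abs=0.00501
                )
                assert 2 * e / n == pytest.approx(row["mean_degree"], abs=0.00501)

    def test_single_node_connectance_undefined(self):
        g = nx.Graph()
        g.add_node("lonely")
        ts = rz.summarize_topology(Network(g))
        assert math.isnan(ts.connectance)
        assert ts.cluster_count == 1 and ts.node_count == 1


class TestFriedman:
    def test_identical_values_degenerate(self):
        stat, p = rz.friedman_rank_test(np.ones((3, 3)))
        assert stat == 0.0 and p == 1.0

    def test_consistent_ranking_two_methods(self):
        # method A larger in all 3 blocks: statistic = 3.0
        stat, _ = rz.friedman_rank_test(np.array([[2, 1], [5, 3], [9, 4]]))
        assert stat == pytest.approx(3.0)

    def test_matches_scipy_for_three_methods(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=(10, 3))
        stat, p = rz.friedman_rank_test(x)
        ref = stats.friedmanchisquare(x[:, 0], x[:, 1], x[:, 2])
        assert stat == pytest.approx(ref.statistic, rel=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-12)

    def test_chi2_p_close_to_exact_permutation_null(self):
        # 3x3 fixture: enumerate all (3!)^3 within-row permutations
        x = np.array([[1.0, 2.0, 3.0], [2.0, 3.0, 1.0], [1.0, 3.0, 2.0]])
        obs, p_chi2 = rz.friedman_rank_test(x)
        perms = list(itertools.permutations(range(3)))
        count = total = 0
        for pa in perms:
            for pb in perms:
                for pc in perms:
                    arranged = np.vstack([x[0, list(pa)], x[1, list(pb)], x[2, list(pc)]])
                    stat, _ = rz.friedman_rank_test(arranged)
                    total += 1
                    count += stat >= obs - 1e-12
        assert p_chi2 == pytest.approx(count / total, abs=0.1)

    def test_missing_cells_rejected(self):
        with pytest.raises(TableError, match="missing"):
            rz.friedman_rank_test(np.array([[1.0, np.nan], [2.0, 3.0]]))
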