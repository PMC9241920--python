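"""Network construction, topology, modules, ER ensembles, keystones,
Spearman/bipartite association networks."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ecoassembly import (
    OtuTable,
    EnvTable,
    build_network,
    correlation_table,
    topology_stats,
    fit_powerlaw_r2,
    louvain_partition,
    er_random_ensemble,
    identify_keystones,
    sample_subnetworks,
    spearman_network,
    bipartite_incidence,
)


def _corr_df(rows):
    return pd.DataFrame(rows, columns=["id_a", "id_b", "estimate", "p_value"])


class TestBuildNetwork:
    @pytest.mark.parametrize(
        "r,p,kept",
        [
            (0.5, 0.01, False),   # |r| must be strictly greater
            (0.6, 0.01, True),
            (0.6, 0.05, False),   # p must be strictly smaller
            (-0.7, 0.001, True),  # negative correlations kept with sign
        ],
    )
    def test_strict_thresholds(self, r, p, kept):
        net = build_network(_corr_df([("a", "b", r, p)]))
        assert net.has_edge("a", "b") is kept
        if kept:
            assert net["a"]["b"]["sign"] == ("+" if r > 0 else "-")

    def test_isolated_nodes_absent_and_empty_table(self):
        net = build_network(_corr_df([("a", "b", 0.1, 0.9)]))
        assert net.number_of_nodes() == 0
        assert build_network(_corr_df([])).number_of_nodes() == 0

    def test_round_trip_of_matrix_flattening(self):
        ids = ["x", "y", "z"]
        r = pd.DataFrame(np.eye(3), index=ids, columns=ids)
        r.iloc[0, 1] = r.iloc[1, 0] = 0.8
        table = correlation_table(r)
        assert len(table) == 3
        assert table.set_index(["id_a", "id_b"]).loc[("x", "y"), "estimate"] == 0.8


class TestTopology:
    def test_triangle(self):
        st_ = topology_stats(nx.complete_graph(3))
        assert st_.clustering_coefficient == 1.0
        assert st_.diameter == 1
        assert (st_.node_stats["degree"] == 2).all()

    def test_path_graph_hand_enumeration(self):
        # A-B-C-D: diameter 3; B and C each sit on 2 shortest paths
        net = nx.path_graph(["A", "B", "C", "D"])
        st_ = topology_stats(net)
        assert st_.diameter == 3
        assert st_.node_stats.loc["B", "betweenness"] == 2
        assert st_.node_stats.loc["C", "betweenness"] == 2
        assert st_.node_stats.loc["A", "betweenness"] == 0
        assert st_.average_path_length == pytest.approx((3 * 1 + 2 * 2 + 3) / 6)

    def test_star_graph(self):
        net = nx.star_graph(4)  # center 0 + 4 leaves
        st_ = topology_stats(net)
        assert st_.clustering_coefficient == 0.0
        assert st_.node_stats.loc[0, "degree"] == 4
        assert st_.node_stats.loc[0, "betweenness"] == 6  # C(4,2) leaf pairs
        assert st_.diameter == 2

    def test_path_length_on_largest_component(self):
        net = nx.Graph([("a", "b"), ("b", "c"), ("x", "y")])
        st_ = topology_stats(net)
        assert st_.diameter == 2  # a-b-c component

    def test_empty_graph(self):
        st_ = topology_stats(nx.Graph())
        assert st_.n_nodes == 0 and st_.n_edges == 0


class TestPowerlawFit:
    def test_exact_power_law_r2_near_one(self):
        # realize a degree histogram following f(k) ~ k^-2 exactly
        degrees = []
        for k, freq in [(1, 144), (2, 36), (3, 16), (4, 9), (6, 4), (12, 1)]:
            degrees += [k] * freq
        if sum(degrees) % 2:
            degrees.append(1)
        g = nx.Graph(nx.configuration_model(degrees, seed=1))
        assert fit_powerlaw_r2(g) > 0.9

    def test_regular_graph_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            fit_powerlaw_r2(nx.cycle_graph(10))

    def test_er_fits_worse_than_scale_free(self):
        sf = nx.barabasi_albert_graph(300, 2, seed=1)
        er = nx.gnm_random_graph(300, sf.number_of_edges(), seed=1)
        assert fit_powerlaw_r2(sf) > fit_powerlaw_r2(er)


class TestLouvain:
    def test_three_disjoint_cliques_recovered_exactly(self):
        g = nx.disjoint_union_all([nx.complete_graph(5) for _ in range(3)])
        part = louvain_partition(g, seed=0)
        assert part.modularity == pytest.approx(2 / 3, abs=1e-12)
        assert sorted(part.sizes.index) == ["M1", "M2", "M3"]
        assert (part.sizes == 5).all()
        # members of one clique share one module
        for base in (0, 5, 10):
            mods = {part.membership[base + k] for k in range(5)}
            assert len(mods) == 1

    def test_single_clique_trivial_partition(self):
        part = louvain_partition(nx.complete_graph(6), seed=0)
        assert part.modularity <= 0.0 + 1e-12

    def test_seed_determinism(self):
        g = nx.gnm_random_graph(60, 150, seed=3)
        p1 = louvain_partition(g, seed=5)
        p2 = louvain_partition(g, seed=5)
        pd.testing.assert_series_equal(p1.membership.sort_index(),
                                       p2.membership.sort_index())

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            louvain_partition(nx.Graph())


class TestErEnsemble:
    def test_exact_edge_count_and_density(self):
        net = nx.gnm_random_graph(30, 60, seed=1)
        ens = er_random_ensemble(net, n_random=20, seed=2, with_modularity=False)
        assert len(ens.clustering) == 20
        # G(n, m) has exactly m edges by construction; mean clustering of
        # sparse ER is near p = m / C(n,2)
        assert ens.clustering.mean() == pytest.approx(60 / (30 * 29 / 2), abs=0.05)

    def test_clique_z_score_positive(self):
        net = nx.complete_graph(10)
        ens = er_random_ensemble(
            nx.disjoint_union(net, nx.empty_graph(30)),
            n_random=30, seed=3, with_modularity=False)
        assert ens.z_scores["clustering"] > 3

    def test_seed_reproducible(self):
        net = nx.gnm_random_graph(25, 50, seed=4)
        e1 = er_random_ensemble(net, n_random=10, seed=9, with_modularity=False)
        e2 = er_random_ensemble(net, n_random=10, seed=9, with_modularity=False)
        assert np.array_equal(e1.clustering, e2.clustering)

    def test_impossible_edge_count(self):
        # m > C(n,2) cannot arise in a simple graph, so exercise the
        # guard with a multigraph carrying parallel edges
        g = nx.MultiGraph()
        for _ in range(5):
            g.add_edge("a", "b")
        with pytest.raises(ValueError):
            er_random_ensemble(g, n_random=1, seed=0)


class TestKeystones:
    @pytest.mark.parametrize(
        "degree,betweenness,expected",
        [(150, 100, True), (50, 100, False), (150, 6000, False),
         (100, 100, False), (150, 5000, False)],  # thresholds strict
    )
    def test_threshold_semantics(self, monkeypatch, degree, betweenness, expected):
        import ecoassembly.networks as mod

        net = nx.Graph([("hub", "x")])
        stats_df = pd.DataFrame(
            {"degree": [degree, 1], "betweenness": [betweenness, 0],
             "clustering": [0.0, 0.0]},
            index=["hub", "x"])

        class FakeStats:
            node_stats = stats_df

        monkeypatch.setattr(mod, "topology_stats", lambda net: FakeStats)
        assert ("hub" in identify_keystones(net)) is expected


class TestSubnetworks:
    @pytest.fixture
    def net_and_table(self):
        net = nx.Graph([("A", "B"), ("B", "C"), ("C", "D"), ("A", "C")])
        data = pd.DataFrame(
            [[1, 1, 1, 1], [1, 0, 0, 0], [1, 1, 0, 0], [1, 1, 1, 0]],
            index=["all", "single", "two", "three"],
            columns=["A", "B", "C", "D"])
        return net, OtuTable(data)

    def test_full_sample_is_whole_network(self, net_and_table):
        net, table = net_and_table
        stats_df = sample_subnetworks(net, table)
        assert stats_df.loc["all", "n_edges"] == net.number_of_edges()

    def test_single_taxon_sample_has_no_edges(self, net_and_table):
        net, table = net_and_table
        stats_df = sample_subnetworks(net, table)
        assert stats_df.loc["single", "n_nodes"] == 1
        assert stats_df.loc["single", "n_edges"] == 0

    def test_nested_samples_monotone_edges(self, net_and_table):
        net, table = net_and_table
        stats_df = sample_subnetworks(net, table)
        edges = stats_df.loc[["single", "two", "three", "all"], "n_edges"]
        assert (edges.diff().dropna() >= 0).all()

    def test_node_missing_from_table_rejected(self, net_and_table):
        net, table = net_and_table
        net.add_edge("A", "ZZ")
        with pytest.raises(KeyError, match="ZZ"):
            sample_subnetworks(net, table)


class TestSpearmanNetwork:
    def _tables(self, y_of_x):
        rng = np.random.default_rng(0)
        x = rng.normal(size=30)
        a = OtuTable(pd.DataFrame(
            {"TX": np.argsort(np.argsort(x)) + 1},
            index=[f"s{k}" for k in range(30)]))
        env = EnvTable(pd.DataFrame({"var": y_of_x(x)}, index=a.data.index))
        return a, env

    def test_monotone_transforms(self):
        a, env = self._tables(lambda x: 2 * x + 3)
        corr, net = spearman_network(a, env, rho_min=0.6, q_max=0.05)
        assert corr.estimate.iloc[0] == pytest.approx(1.0)
        assert net.has_edge("TX", "var")
        a, env = self._tables(lambda x: -(x**3))
        corr, _ = spearman_network(a, env, rho_min=0.6, q_max=0.05)
        assert corr.estimate.iloc[0] == pytest.approx(-1.0)

    def test_tied_midranks_match_hand_ranking(self):
        x = np.array([1, 2, 2, 3, 5])
        y = np.array([2, 1, 4, 4, 4])
        # hand-assigned midranks
        rx = np.array([1, 2.5, 2.5, 4, 5])
        ry = np.array([2, 1, 4, 4, 4])
        expected = np.corrcoef(rx, ry)[0, 1]
        a = OtuTable(pd.DataFrame({"TX": x}, index=[f"s{k}" for k in range(5)]))
        env = EnvTable(pd.DataFrame({"var": y}, index=a.data.index))
        corr, _ = spearman_network(a, env, rho_min=0.0, q_max=1.1)
        assert corr.estimate.iloc[0] == pytest.approx(expected, abs=1e-12)

    def test_constant_column_skipped_with_warning(self):
        a = OtuTable(pd.DataFrame({"TX": [1, 2, 3, 4]},
                                  index=[f"s{k}" for k in range(4)]))
        env = EnvTable(pd.DataFrame({"flat": [7.0] * 4, "ok": [1.0, 2, 3, 4]},
                                    index=a.data.index))
        with pytest.warns(UserWarning, match="constant"):
            corr, _ = spearman_network(a, env, rho_min=0.0, q_max=1.1)
        assert set(corr.id_b) == {"ok"}

    def test_bh_adjustment_monotone_and_bounded(self):
        rng = np.random.default_rng(1)
        a = OtuTable(pd.DataFrame(
            rng.integers(0, 50, size=(25, 6)),
            index=[f"s{k}" for k in range(25)],
            columns=[f"T{k}" for k in range(6)]))
        env = EnvTable(pd.DataFrame(rng.normal(size=(25, 3)),
                                    index=a.data.index,
                                    columns=["e1", "e2", "e3"]))
        corr, _ = spearman_network(a, env, rho_min=0.0, q_max=1.1)
        assert (corr.q_value >= corr.p_value - 1e-12).all()
        assert (corr.q_value <= 1).all()

    def test_misaligned_samples_rejected(self):
        a = OtuTable(pd.DataFrame({"TX": [1, 2]}, index=["s1", "s2"]))
        env = EnvTable(pd.DataFrame({"v": [1.0, 2.0]}, index=["s2", "s1"]))
        with pytest.raises(ValueError, match="identically ordered"):
            spearman_network(a, env)


class TestBipartiteIncidence:
    def test_counting_and_incidence(self):
        corr = pd.DataFrame(
            [("p1", "e1", 0.9, 0.001), ("p2", "e1", 0.8, 0.001),
             ("p3", "e1", -0.7, 0.001), ("p1", "e2", 0.9, 0.001)],
            columns=["id_a", "id_b", "estimate", "p_value"])
        incidence, counts = bipartite_incidence(corr, ["p1", "p2", "p3"], ["e1", "e2"])
        assert counts.loc["e1"].sum() == 3
        assert incidence.loc["e1", "p1"] == 1
        assert incidence.loc["e2", "p2"] == 0

    def test_empty_table_all_zero(self):
        corr = pd.DataFrame(columns=["id_a", "id_b", "estimate", "p_value"])
        incidence, counts = bipartite_incidence(corr, ["p1"], ["e1"])
        assert incidence.to_numpy().sum() == 0

    def test_within_set_pair_rejected(self):
        corr = pd.DataFrame([("p1", "p2", 0.9, 0.001)],
                            columns=["id_a", "id_b", "estimate", "p_value"])
        with pytest.raises(ValueError, match="span"):
            bipartite_incidence(corr, ["p1", "p2"], ["e1"])

    def test_overlapping_sets_rejected(self):
        corr = pd.DataFrame(columns=["id_a", "id_b", "estimate", "p_value"])
        with pytest.raises(ValueError, match="disjoint"):
            bipartite_incidence(corr, ["p1"], ["p1"])
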