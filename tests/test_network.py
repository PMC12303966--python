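"""Network construction, topology, roles, robustness, and complexity."""

import warnings

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from standnet import network as net
from standnet.tables import AbundanceTable


def _table(counts: pd.DataFrame, domain="bacteria") -> AbundanceTable:
    return AbundanceTable(
        counts=counts,
        taxonomy=pd.Series("k__;p__", index=counts.columns),
        domain=domain,
    )


def _net_from_graph(g: nx.Graph) -> net.CooccurrenceNetwork:
    for _, _, d in g.edges(data=True):
        d.setdefault("sign", 1)
    return net.CooccurrenceNetwork(graph=g)


class TestFilterAsvs:
    def test_occurrence_bar(self, toy_abundance):
        # A2 present in 2/10 samples (0.2, not strictly above 1/5) -> removed
        kept = net.filter_asvs(toy_abundance)
        assert "A2" not in kept.counts.columns

    def test_abundance_bar(self):
        counts = pd.DataFrame(
            {
                "big": [10_000] * 10,
                "tiny": [1, 1, 1, 1, 1, 1, 1, 1, 1, 1],  # ~0.01% mean, not above
            },
            index=[f"s{i}" for i in range(10)],
        )
        kept = net.filter_asvs(_table(counts))
        assert list(kept.counts.columns) == ["big"]

    def test_toy_table_matches_hand_enumeration(self, toy_abundance):
        # A1, A3, A5 are everywhere and abundant; A2, A4 fail occurrence
        kept = net.filter_asvs(toy_abundance)
        assert list(kept.counts.columns) == ["A1", "A3", "A5"]

    def test_everything_filtered_raises(self, toy_abundance):
        with pytest.raises(ValueError, match="relax"):
            net.filter_asvs(
                toy_abundance,
                net.FilterPolicy(min_mean_relative_abundance=0.9),
            )


class TestSpearmanEdges:
    def test_perfect_monotone_pairs(self):
        counts = pd.DataFrame(
            {
                "up": [1, 2, 3, 4, 5, 6],
                "up2": [2, 4, 8, 16, 32, 64],
                "down": [60, 50, 40, 30, 20, 10],
            }
        )
        r, _ = net.spearman_edges(counts)
        assert r.loc["up", "up2"] == pytest.approx(1.0)
        assert r.loc["up", "down"] == pytest.approx(-1.0)

    def test_tie_handling_matches_rank_formula(self):
        # one tie in x; oracle = Pearson correlation of average ranks
        x = np.array([1, 2, 2, 4, 5, 6], dtype=float)
        y = np.array([3, 1, 4, 1, 5, 9], dtype=float)
        counts = pd.DataFrame({"x": x, "y": y})
        r, _ = net.spearman_edges(counts)
        oracle = np.corrcoef(stats.rankdata(x), stats.rankdata(y))[0, 1]
        assert r.loc["x", "y"] == pytest.approx(oracle, abs=1e-12)

    def test_constant_asv_flagged_nan(self):
        counts = pd.DataFrame({"a": [1, 2, 3, 4], "c": [5, 5, 5, 5]})
        with pytest.warns(UserWarning, match="constant"):
            r, p = net.spearman_edges(counts)
        assert np.isnan(r.loc["a", "c"]) and np.isnan(p.loc["a", "c"])


class TestBhAdjust:
    @pytest.mark.parametrize(
        "p, expected",
        [
            ([0.03], [0.03]),
            ([0.01, 0.02, 0.03], [0.03, 0.03, 0.03]),
            ([0.01, 0.04], [0.02, 0.04]),
        ],
    )
    def test_hand_step_up(self, p, expected):
        assert net.bh_adjust(p) == pytest.approx(expected)

    def test_monotone_in_p_rank_and_bounded(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0, 1, 50)
        q = net.bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()
        assert (q <= 1).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            net.bh_adjust([0.5, 1.2])


class TestBuildNetwork:
    def test_correlated_pair_plus_noise(self):
        rng = np.random.default_rng(1)
        n = 30
        a = rng.integers(10, 100, n)
        counts = pd.DataFrame(
            {"a": a, "b": a * 2 + 1, "noise": rng.permutation(np.arange(10, 10 + n))}
        )
        built = net.build_network(_table(counts), prefiltered=True)
        assert built.graph.number_of_edges() == 1
        assert built.graph.number_of_nodes() == 2
        assert built.graph.has_edge("a", "b")
        assert built.n_candidates == 3

    def test_edges_satisfy_policy_and_no_self_loops(self, abundance_tables):
        bacteria, _ = abundance_tables
        built = net.build_network(bacteria)
        policy = net.EdgePolicy()
        for u, v, d in built.graph.edges(data=True):
            assert u != v
            assert abs(d["r"]) > policy.r_threshold
            assert d["q"] < policy.alpha
            assert d["sign"] == (1 if d["r"] > 0 else -1)

    def test_raw_p_mode_never_fewer_edges(self, abundance_tables):
        bacteria, _ = abundance_tables
        adjusted = net.build_network(bacteria, edge_policy=net.EdgePolicy())
        raw = net.build_network(
            bacteria, edge_policy=net.EdgePolicy(use_adjusted=False)
        )
        assert raw.graph.number_of_edges() >= adjusted.graph.number_of_edges()

    def test_shuffled_null_has_almost_no_edges(self, abundance_tables):
        """Independently permuting each ASV's counts destroys the planted
        correlation structure, so the null edge count collapses."""
        bacteria, _ = abundance_tables
        block_edges = net.build_network(bacteria).graph.number_of_edges()
        null_counts = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            shuffled = bacteria.counts.apply(
                lambda c: rng.permutation(c.to_numpy()), axis=0
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                built = net.build_network(
                    _table(shuffled), prefiltered=False
                )
            null_counts.append(built.graph.number_of_edges())
        assert np.mean(null_counts) < 0.01 * block_edges


class TestTopology:
    def test_complete_graph_closed_forms(self):
        for n in range(3, 7):
            topo = net.topology(_net_from_graph(nx.complete_graph(n)))
            assert topo.density == pytest.approx(1.0)
            assert topo.average_degree == pytest.approx(n - 1)
            assert topo.diameter == 1
            assert topo.average_clustering == pytest.approx(1.0)
            assert topo.average_path_length == pytest.approx(1.0)

    def test_path_graph_distances(self):
        topo = net.topology(_net_from_graph(nx.path_graph(4)))
        assert topo.diameter == 3
        assert topo.average_path_length == pytest.approx(10 / 6)

    def test_two_triangles_modularity(self):
        g = nx.Graph()
        g.add_edges_from([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])
        topo = net.topology(_net_from_graph(g), seed=0)
        assert topo.modularity == pytest.approx(0.5)
        # the natural partition: each triangle its own module
        mods = topo.modules
        assert mods[0] == mods[1] == mods[2]
        assert mods[3] == mods[4] == mods[5]
        assert mods[0] != mods[3]
        assert not topo.connected

    def test_empty_network_flagged(self):
        topo = net.topology(net.CooccurrenceNetwork(graph=nx.Graph()))
        assert topo.n_nodes == 0 and topo.n_edges == 0


class TestZiPi:
    def test_all_links_internal_pi_zero(self):
        g = nx.complete_graph(4)
        roles = net.zipi(g, {i: 0 for i in g.nodes})
        assert (roles["pi"] == 0).all()

    def test_even_two_module_split_pi_half(self):
        g = nx.Graph()
        g.add_edges_from([("x", "a1"), ("x", "a2"), ("x", "b1"), ("x", "b2")])
        modules = {"x": 0, "a1": 0, "a2": 0, "b1": 1, "b2": 1}
        roles = net.zipi(g, modules)
        assert roles.loc["x", "pi"] == pytest.approx(0.5)

    def test_mean_degree_node_zi_zero(self):
        g = nx.complete_graph(5)  # all within-module degrees equal
        roles = net.zipi(g, {i: 0 for i in g.nodes})
        assert np.allclose(roles["zi"], 0.0)

    def test_roles_partition_with_exact_thresholds(self):
        rows = []
        for zi, pi in [(2.5, 0.62), (2.5, 0.61), (2.4, 0.62), (0.0, 0.0)]:
            role = (
                "network hub" if zi >= 2.5 and pi >= 0.62
                else "module hub" if zi >= 2.5
                else "connector" if pi >= 0.62
                else "peripheral"
            )
            rows.append(role)
        assert rows == ["network hub", "module hub", "connector", "peripheral"]
        # and the implementation agrees on a real partitioned graph
        g = nx.barbell_graph(6, 0)
        modules = {i: (0 if i < 6 else 1) for i in g.nodes}
        roles = net.zipi(g, modules)
        assert set(roles["role"]) <= {
            "peripheral", "module hub", "connector", "network hub"
        }
        assert len(roles) == g.number_of_nodes()

    def test_incomplete_partition_rejected(self):
        g = nx.path_graph(3)
        with pytest.raises(ValueError):
            net.zipi(g, {0: 0, 1: 0})


class TestKeystoneAbundance:
    def _roles(self, mapping):
        return pd.DataFrame(
            {"role": pd.Series(mapping)}, index=list(mapping)
        )

    def test_all_keystone_gives_one(self, toy_abundance):
        roles = self._roles({a: "connector" for a in toy_abundance.counts.columns})
        frac = net.keystone_abundance(toy_abundance, roles)
        assert np.allclose(frac, 1.0)

    def test_no_keystone_gives_zero_with_warning(self, toy_abundance):
        roles = self._roles({a: "peripheral" for a in toy_abundance.counts.columns})
        with pytest.warns(UserWarning):
            frac = net.keystone_abundance(toy_abundance, roles)
        assert np.allclose(frac, 0.0)

    def test_hand_computed_fractions(self):
        counts = pd.DataFrame(
            {"k1": [10, 0], "k2": [10, 5], "o1": [20, 5], "o2": [60, 0]},
            index=["s1", "s2"],
        )
        roles = self._roles(
            {"k1": "module hub", "k2": "connector", "o1": "peripheral", "o2": "peripheral"}
        )
        frac = net.keystone_abundance(_table(counts), roles)
        assert frac["s1"] == pytest.approx(20 / 100)
        assert frac["s2"] == pytest.approx(5 / 10)


class TestRobustness:
    def test_complete_graph_half_removal_exact(self):
        rc = net.robustness(
            _net_from_graph(nx.complete_graph(10)),
            "random", 0.5, n_replicates=20, seed=0,
        )
        assert rc.mean_remaining[0] == pytest.approx(0.5)
        assert rc.sd_remaining[0] == 0.0

    def test_star_targeted_hub_removal_kills_all(self):
        g = nx.star_graph(9)  # node 0 is the hub
        rc = net.robustness(
            _net_from_graph(g), "hubs", 0.2, n_replicates=5, seed=0
        )
        assert rc.mean_remaining[0] == 0.0

    def test_monte_carlo_matches_independent_simulation(self):
        """G(100, 0.05): mean remaining fraction agrees with a from-scratch
        simulation that never touches the implementation's code path."""
        g = nx.gnp_random_graph(100, 0.05, seed=12)
        rc = net.robustness(
            _net_from_graph(g), "random", 0.5, n_replicates=400, seed=1
        )
        # independent oracle: adjacency-matrix simulation
        adj = nx.to_numpy_array(g)
        rng = np.random.default_rng(99)
        props = []
        for _ in range(4000):
            keep = rng.choice(100, size=50, replace=False)
            sub = adj[np.ix_(keep, keep)]
            props.append((sub.sum(axis=1) > 0).sum() / 100)
        mc_se = rc.sd_remaining[0] / np.sqrt(400)
        oracle_se = np.std(props, ddof=1) / np.sqrt(len(props))
        assert abs(rc.mean_remaining[0] - np.mean(props)) < 3 * (oracle_se + mc_se)

    def test_curve_starts_at_one_and_decreases(self):
        g = nx.gnp_random_graph(60, 0.1, seed=3)
        g.remove_nodes_from(list(nx.isolates(g)))
        rc = net.robustness_curve(
            _net_from_graph(g),
            fractions=[0.0, 0.2, 0.5, 0.8],
            n_replicates=40,
            seed=2,
        )
        assert rc.mean_remaining[0] == pytest.approx(1.0)
        assert (np.diff(rc.mean_remaining) <= 0.05).all()

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError):
            net.robustness(_net_from_graph(nx.complete_graph(4)), "random", 1.5)


class TestSubnetworkComplexity:
    def test_identical_subgraphs_score_zero(self):
        g = nx.complete_graph(4)
        g = nx.relabel_nodes(g, {i: f"A{i}" for i in range(4)})
        counts = pd.DataFrame(
            np.ones((3, 4), dtype=int),
            index=["s1", "s2", "s3"],
            columns=[f"A{i}" for i in range(4)],
        )
        c = net.subnetwork_complexity(_net_from_graph(g), _table(counts))
        assert np.allclose(c, 0.0)

    def test_clique_sample_beats_sparse_sample(self):
        g = nx.Graph()
        g.add_edges_from([("A0", "A1"), ("A0", "A2"), ("A1", "A2")])  # triangle
        g.add_edge("A3", "A4")
        counts = pd.DataFrame(
            {
                "A0": [5, 5], "A1": [5, 0], "A2": [5, 0],
                "A3": [0, 5], "A4": [0, 5],
            },
            index=["clique", "sparse"],
        )
        c = net.subnetwork_complexity(_net_from_graph(g), _table(counts))
        assert c["clique"] > c["sparse"]

    def test_hand_computed_zscore_means(self):
        g = nx.Graph()
        g.add_edges_from(
            [("A", "B"), ("B", "C"), ("A", "C"), ("C", "D"), ("D", "E"), ("E", "F")]
        )
        presence = {
            "s1": ["A", "B", "C"],          # triangle: deg 2, dens 1, clust 1
            "s2": ["C", "D", "E", "F"],     # path: deg 1.5, dens 0.5, clust 0
            "s3": ["A", "B", "C", "D"],     # triangle + pendant
        }
        counts = pd.DataFrame(
            [[int(a in present) for a in "ABCDEF"] for present in presence.values()],
            index=list(presence),
            columns=list("ABCDEF"),
        )
        c = net.subnetwork_complexity(_net_from_graph(g), _table(counts))
        # oracle: recompute panel by hand
        panel = {
            "s1": (2.0, 1.0, 1.0),
            "s2": (6 / 4, 0.5, 0.0),
            "s3": (2.0, 4 / 6, np.mean([1, 1, 1 / 3, 0])),
        }
        raw = pd.DataFrame(panel, index=["average_degree", "density", "average_clustering"]).T
        z = (raw - raw.mean()) / raw.std(ddof=1)
        expected = z.mean(axis=1)
        for s in presence:
            assert c[s] == pytest.approx(expected[s], abs=1e-12)

    def test_sample_with_too_few_nodes_is_nan(self):
        g = nx.complete_graph(3)
        g = nx.relabel_nodes(g, {i: f"A{i}" for i in range(3)})
        counts = pd.DataFrame(
            {"A0": [1, 1], "A1": [1, 0], "A2": [1, 0]}, index=["full", "lonely"]
        )
        c = net.subnetwork_complexity(_net_from_graph(g), _table(counts))
        assert np.isnan(c["lonely"])
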