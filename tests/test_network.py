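"""Correlation matrices, network thresholds, topology statistics."""

import numpy as np
import pytest
from scipy import stats

from irca.core import IrcaError
from irca.network import (
    IRCN,
    CorrelationMatrix,
    build_ircn,
    connected_modules,
    correlation_matrix,
    delta_rho,
    network_stats,
    pearson_with_p,
    top_degree_peaks,
)


class TestPearson:
    def test_perfect_anticorrelation(self):
        r, p = pearson_with_p([1, 2, 3], [3, 2, 1])
        assert r == -1.0 and p == 0.0

    def test_perfect_correlation(self):
        r, p = pearson_with_p([1, 2, 3], [1, 2, 3])
        assert r == 1.0 and p == 0.0

    def test_hand_computed_value(self):
        # dx=[-2,-1,0,1,2], dy=[-1.2,-2.2,0.8,-0.2,2.8]:
        # sum dx*dy = 10, sum dx^2 = 10, sum dy^2 = 14.8 -> 10/sqrt(148)
        r, p = pearson_with_p([1, 2, 3, 4, 5], [2, 1, 4, 3, 6])
        assert r == pytest.approx(10 / np.sqrt(148), abs=1e-12)

    def test_matches_scipy_reference(self, rng):
        for _ in range(20):
            x = rng.standard_normal(15)
            y = rng.standard_normal(15)
            r, p = pearson_with_p(x, y)
            ref = stats.pearsonr(x, y)
            assert r == pytest.approx(ref.statistic, abs=1e-12)
            assert p == pytest.approx(ref.pvalue, abs=1e-9)

    def test_zero_variance_flags_nan(self):
        r, p = pearson_with_p([1, 1, 1], [1, 2, 3])
        assert np.isnan(r) and np.isnan(p)


class TestCorrelationMatrix:
    def test_pair_count_on_instrument_grid(self):
        """1,581 features enumerate C(1581,2) = 1,248,990 pairs —
        over one million pairwise correlations."""
        labels = [str(w) for w in range(1581)]
        cm = CorrelationMatrix(labels, np.eye(1581), np.eye(1581), 60)
        assert cm.n_pairs == 1_248_990
        assert cm.n_pairs > 1_000_000

    def test_duplicated_column_correlates_at_one(self, rng):
        X = rng.standard_normal((10, 4))
        X[:, 3] = X[:, 0]
        cm = correlation_matrix(X)
        assert cm.rho[0, 3] == pytest.approx(1.0, abs=1e-12)

    def test_matches_brute_force_per_pair_loop(self, rng):
        """Vectorized all-pairs path equals an independent per-pair
        scipy.stats.pearsonr loop elementwise."""
        X = rng.standard_normal((10, 50))
        cm = correlation_matrix(X)
        for i in range(50):
            for j in range(i + 1, 50):
                ref = stats.pearsonr(X[:, i], X[:, j])
                assert abs(cm.rho[i, j] - ref.statistic) < 1e-12
                assert abs(cm.pval[i, j] - ref.pvalue) < 1e-9

    def test_constant_column_yields_nan_pairs(self, rng):
        X = rng.standard_normal((8, 3))
        X[:, 1] = 2.0
        with pytest.warns(UserWarning, match="constant"):
            cm = correlation_matrix(X)
        assert np.isnan(cm.rho[0, 1]) and np.isnan(cm.rho[1, 2])
        assert np.isfinite(cm.rho[0, 2])

    def test_too_few_cells_rejected(self, rng):
        with pytest.raises(IrcaError):
            correlation_matrix(rng.standard_normal((2, 5)))


def cm_from(rho_pairs, pval_pairs, features):
    f = len(features)
    rho = np.eye(f)
    pv = np.full((f, f), 1.0)
    for (i, j), r in rho_pairs.items():
        rho[i, j] = rho[j, i] = r
    for (i, j), p in pval_pairs.items():
        pv[i, j] = pv[j, i] = p
    return CorrelationMatrix(list(features), rho, pv, 60)


class TestBuildIrcn:
    def test_all_zero_rho_gives_empty_network(self):
        cm = cm_from({}, {}, ["a", "b", "c"])
        g = build_ircn(cm)
        assert g.graph.number_of_edges() == 0

    def test_joint_predicate(self):
        cm = cm_from(
            {(0, 1): -0.8, (0, 2): -0.7, (1, 2): 0.9},
            {(0, 1): 0.01, (0, 2): 0.2, (1, 2): 0.001},
            ["a", "b", "c"],
        )
        g = build_ircn(cm, "strong_negative", -0.6, 0.05)
        assert set(map(frozenset, g.graph.edges)) == {frozenset({"a", "b"})}

    def test_threshold_monotonicity(self, rng):
        X = rng.standard_normal((12, 30))
        cm = correlation_matrix(X)
        loose = build_ircn(cm, "strong_negative", -0.3, 0.2)
        tight_rho = build_ircn(cm, "strong_negative", -0.6, 0.2)
        tight_alpha = build_ircn(cm, "strong_negative", -0.3, 0.05)
        loose_edges = set(map(frozenset, loose.graph.edges))
        assert set(map(frozenset, tight_rho.graph.edges)) <= loose_edges
        assert set(map(frozenset, tight_alpha.graph.edges)) <= loose_edges

    def test_strong_negative_subset_of_significant(self, rng):
        X = rng.standard_normal((12, 30))
        cm = correlation_matrix(X)
        strong = build_ircn(cm, "strong_negative", -0.3, 0.1)
        sig = build_ircn(cm, "significant", alpha=0.1)
        assert (set(map(frozenset, strong.graph.edges))
                <= set(map(frozenset, sig.graph.edges)))

    def test_nan_pairs_never_kept(self, rng):
        X = rng.standard_normal((8, 4))
        X[:, 0] = 1.0
        with pytest.warns(UserWarning):
            cm = correlation_matrix(X)
        g = build_ircn(cm, "significant", alpha=0.99)
        assert all("f0" not in e for e in map(set, g.graph.edges))

    def test_invalid_thresholds_rejected(self):
        cm = cm_from({}, {}, ["a", "b"])
        with pytest.raises(IrcaError):
            build_ircn(cm, "strong_negative", rho_threshold=0.3)
        with pytest.raises(IrcaError):
            build_ircn(cm, alpha=1.5)
        with pytest.raises(IrcaError):
            build_ircn(cm, mode="causal")


class DSU:
    """Union-find oracle for connected components."""

    def __init__(self):
        self.parent = {}

    def find(self, x):
        self.parent.setdefault(x, x)
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        self.parent[self.find(a)] = self.find(b)


class TestModulesAndStats:
    def test_two_disjoint_edges_two_modules(self):
        cm = cm_from({(0, 1): -0.9, (2, 3): -0.9},
                     {(0, 1): 0.001, (2, 3): 0.001},
                     ["a", "b", "c", "d"])
        mods = connected_modules(build_ircn(cm))
        assert [len(m) for m in mods] == [2, 2]

    def test_path_is_one_module(self):
        cm = cm_from({(0, 1): -0.9, (1, 2): -0.9},
                     {(0, 1): 0.001, (1, 2): 0.001},
                     ["a", "b", "c"])
        mods = connected_modules(build_ircn(cm))
        assert [len(m) for m in mods] == [3]

    def test_random_graph_matches_union_find_oracle(self, rng):
        import networkx as nx

        g = nx.Graph()
        nodes = [str(i) for i in range(200)]
        g.add_nodes_from([])
        dsu = DSU()
        for _ in range(150):
            a, b = rng.choice(200, 2, replace=False)
            g.add_edge(nodes[a], nodes[b], rho=-0.7)
            dsu.union(nodes[a], nodes[b])
        ircn = IRCN(g, "strong_negative", -0.6, 0.05, 200, nodes)
        mods = connected_modules(ircn)
        groups = {}
        for x in g.nodes:
            groups.setdefault(dsu.find(x), set()).add(x)
        assert sorted(map(len, mods), reverse=True) == sorted(
            map(len, groups.values()), reverse=True)
        assert {frozenset(m) for m in mods} == {
            frozenset(s) for s in groups.values()}

    def test_density_and_degree_hand_values(self):
        # 4 incident nodes, 3 edges: density 3/6, ave_degree 6/4
        cm = cm_from({(0, 1): -0.9, (1, 2): -0.9, (2, 3): -0.9},
                     {(0, 1): 0.001, (1, 2): 0.001, (2, 3): 0.001},
                     ["a", "b", "c", "d", "e"])
        st_ = network_stats(build_ircn(cm))
        assert st_.num_node == 4 and st_.num_edge == 3
        assert st_.density == pytest.approx(0.5)
        assert st_.ave_degree == pytest.approx(1.5)

    def test_complete_graph_density_one(self):
        pairs = {(i, j): -0.9 for i in range(5) for j in range(i + 1, 5)}
        pvals = {k: 0.001 for k in pairs}
        st_ = network_stats(build_ircn(cm_from(pairs, pvals, list("abcde"))))
        assert st_.density == 1.0

    def test_ave_pcc_pair_denominator(self):
        # kept rho {-0.8, -0.7} among 5 total features -> -1.5 / C(5,2)
        cm = cm_from({(0, 1): -0.8, (2, 3): -0.7},
                     {(0, 1): 0.001, (2, 3): 0.001},
                     list("abcde"))
        g = build_ircn(cm)
        assert network_stats(g).ave_pcc == pytest.approx(-1.5 / 10)
        assert network_stats(g, "nodes").ave_pcc == pytest.approx(-1.5 / 4)

    def test_empty_graph_reports_zeros(self):
        st_ = network_stats(build_ircn(cm_from({}, {}, ["a", "b"])))
        assert (st_.num_node, st_.num_edge, st_.num_module) == (0, 0, 0)
        assert st_.density == 0.0 and st_.ave_degree == 0.0

    def test_internal_consistency_on_random_graphs(self, rng):
        """Sum of module sizes = num_node; ave_degree * N = 2E;
        density in [0,1] — over 100 random correlation matrices."""
        for seed in range(100):
            r2 = np.random.default_rng(seed)
            X = r2.standard_normal((10, 20))
            g = build_ircn(correlation_matrix(X), "strong_negative",
                           -0.3, 0.3)
            st_ = network_stats(g)
            mods = connected_modules(g)
            assert sum(map(len, mods)) == st_.num_node
            assert st_.num_module == len(mods)
            if st_.num_node:
                assert st_.ave_degree * st_.num_node == pytest.approx(
                    2 * st_.num_edge)
            assert 0.0 <= st_.density <= 1.0
            assert st_.size_largest_module <= st_.num_node
            assert st_.ave_pcc <= 0.0


class TestTopDegree:
    def make_star(self):
        center = "1000"
        leaves = [str(w) for w in (700, 800, 900, 1100)]
        pairs, pvals = {}, {}
        feats = [center] + leaves
        for i in range(1, 5):
            pairs[(0, i)] = -0.9
            pvals[(0, i)] = 0.001
        return build_ircn(cm_from(pairs, pvals, feats))

    def test_star_center_ranks_first(self):
        g = self.make_star()
        ranked = top_degree_peaks(g)
        assert ranked[0] == ("1000", 4)

    def test_ties_break_by_ascending_wavenumber(self):
        g = self.make_star()
        tail = top_degree_peaks(g)[1:]
        assert [x for x, _ in tail] == ["700", "800", "900", "1100"]

    def test_k_beyond_module_size_returns_all(self):
        g = self.make_star()
        assert len(top_degree_peaks(g, k=50)) == 5

    def test_matches_brute_force_degrees(self, rng):
        X = rng.standard_normal((10, 25))
        g = build_ircn(correlation_matrix(X), "strong_negative", -0.2, 0.5)
        counts = {}
        for a, b in g.graph.edges:
            counts[a] = counts.get(a, 0) + 1
            counts[b] = counts.get(b, 0) + 1
        for feat, deg in top_degree_peaks(g):
            assert counts[feat] == deg


class TestDeltaRho:
    def test_printed_extremes_give_1_18(self):
        """A pair swinging from rho 0.619 down to -0.557 across a time
        series has delta-rho 1.176, i.e. 1.18 at two decimals."""
        feats = ["1441", "1402"]
        series = [
            cm_from({(0, 1): 0.619}, {(0, 1): 0.001}, feats),
            cm_from({(0, 1): 0.1}, {(0, 1): 0.5}, feats),
            cm_from({(0, 1): -0.557}, {(0, 1): 0.002}, feats),
        ]
        dm = delta_rho(series)
        assert dm.pair("1441", "1402") == pytest.approx(1.176, abs=1e-12)
        assert round(dm.pair("1441", "1402"), 2) == 1.18
        assert dm.argmax_t[0, 1] == 0 and dm.argmin_t[0, 1] == 2

    def test_constant_rho_gives_zero(self):
        feats = ["a", "b"]
        series = [cm_from({(0, 1): 0.4}, {}, feats)] * 3
        assert delta_rho(series).pair("a", "b") == 0.0

    def test_two_point_swing(self):
        feats = ["a", "b"]
        series = [cm_from({(0, 1): -0.5}, {}, feats),
                  cm_from({(0, 1): 0.5}, {}, feats)]
        assert delta_rho(series).pair("a", "b") == pytest.approx(1.0)

    def test_nan_time_points_skipped(self):
        feats = ["a", "b"]
        good = cm_from({(0, 1): 0.3}, {}, feats)
        bad = cm_from({}, {}, feats)
        bad.rho[0, 1] = bad.rho[1, 0] = np.nan
        with pytest.warns(UserWarning):
            dm = delta_rho([good, bad, cm_from({(0, 1): -0.2}, {}, feats)])
        assert dm.pair("a", "b") == pytest.approx(0.5)

    def test_mismatched_features_rejected(self):
        with pytest.raises(IrcaError):
            delta_rho([cm_from({}, {}, ["a", "b"]),
                       cm_from({}, {}, ["a", "c"])])
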