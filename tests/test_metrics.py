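"""Graph-metric correctness against closed forms and brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import hubdisrupt as hd

import bruteforce as bf


def _net(adj, s=0.3):
    return hd.BinaryNetwork(np.asarray(adj, dtype=np.int8), sparsity=s)


def complete(n):
    a = np.ones((n, n), dtype=np.int8)
    np.fill_diagonal(a, 0)
    return _net(a)


def path3():
    return _net([[0, 1, 0], [1, 0, 1], [0, 1, 0]])


def star4():
    a = np.zeros((4, 4), dtype=np.int8)
    a[0, 1:] = a[1:, 0] = 1
    return _net(a)


def triangle_plus_pendant():
    # vertices 0-1-2 form a triangle; 3 hangs off vertex 0
    a = np.zeros((4, 4), dtype=np.int8)
    for i, j in [(0, 1), (0, 2), (1, 2), (0, 3)]:
        a[i, j] = a[j, i] = 1
    return _net(a)


class TestClosedForms:
    def test_complete_graph_everything_saturates(self):
        net = complete(10)
        glob, nodal = hd.all_metrics(net)
        assert glob.L == 1.0
        assert glob.E_glob == 1.0
        assert glob.C == 1.0
        assert np.all(nodal.degree == 9)
        assert np.all(nodal.betweenness == 0.0)
        assert np.all(nodal.local_efficiency == 1.0)

    def test_three_node_path(self):
        net = path3()
        assert hd.characteristic_path_length(net) == pytest.approx(4 / 3)
        assert hd.global_efficiency(net) == pytest.approx(5 / 6)
        assert hd.betweenness_centrality(net).tolist() == [0.0, 1.0, 0.0]

    def test_four_node_star(self):
        net = star4()
        assert hd.characteristic_path_length(net) == pytest.approx(1.5)
        b = hd.betweenness_centrality(net)
        assert b[0] == pytest.approx(3.0)  # three leaf pairs via the hub
        assert np.all(b[1:] == 0.0)
        assert np.all(hd.local_efficiency(net) == 0.0)  # leaves and hollow hub

    def test_triangle_plus_pendant(self):
        net = triangle_plus_pendant()
        c = hd.nodal_clustering(net)
        assert c[0] == pytest.approx(1 / 3)   # one edge among three neighbours
        assert c[1] == c[2] == pytest.approx(1.0)
        assert c[3] == 0.0
        assert hd.mean_clustering(net) == pytest.approx(7 / 12)
        e = hd.local_efficiency(net)
        assert e[0] == pytest.approx(1 / 3)
        assert e[3] == 0.0  # degree-1 convention

    def test_tree_has_no_clustering(self):
        a = np.zeros((6, 6), dtype=np.int8)
        for i, j in [(0, 1), (0, 2), (1, 3), (1, 4), (2, 5)]:
            a[i, j] = a[j, i] = 1
        assert np.all(hd.nodal_clustering(_net(a)) == 0.0)

    def test_empty_graph_conventions(self):
        net = _net(np.zeros((4, 4), dtype=np.int8))
        assert hd.global_efficiency(net) == 0.0
        assert hd.mean_clustering(net) == 0.0
        with pytest.raises(ValueError, match="no connected pairs"):
            hd.characteristic_path_length(net)


class TestOracleEquivalence:
    def test_distances_match_floyd_warshall(self):
        rng = np.random.default_rng(10)
        for _ in range(100):
            n = int(rng.integers(3, 13))
            adj = bf.random_graph(n, rng.uniform(0.1, 0.9), rng)
            d = hd.shortest_path_lengths(_net(adj))
            assert np.array_equal(d, bf.fw_distances(adj))

    def test_all_metrics_match_bruteforce(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            n = int(rng.integers(3, 13))
            adj = bf.random_graph(n, rng.uniform(0.1, 0.9), rng)
            net = _net(adj)
            glob, nodal = hd.all_metrics(net)
            L, frac = bf.char_path_length(adj)
            if frac > 0:
                assert glob.L == pytest.approx(L, rel=1e-12)
            assert glob.connected_pair_fraction == pytest.approx(frac, rel=1e-12)
            assert glob.E_glob == pytest.approx(bf.global_efficiency(adj), rel=1e-12)
            assert nodal.degree.tolist() == bf.degrees(adj)
            assert nodal.clustering == pytest.approx(bf.clustering(adj), rel=1e-12)
            assert nodal.betweenness == pytest.approx(bf.betweenness(adj), rel=1e-12)
            assert nodal.local_efficiency == pytest.approx(
                bf.local_efficiency(adj), rel=1e-12)

    def test_betweenness_equals_exhaustive_path_enumeration(self):
        rng = np.random.default_rng(12)
        for _ in range(30):
            n = int(rng.integers(3, 9))
            adj = bf.random_graph(n, rng.uniform(0.2, 0.8), rng)
            ours = hd.betweenness_centrality(_net(adj))
            assert ours == pytest.approx(
                bf.betweenness_by_path_enumeration(adj), rel=1e-12)

    def test_aggregator_consistent_with_individual_ops(self):
        rng = np.random.default_rng(13)
        for _ in range(50):
            n = int(rng.integers(4, 12))
            adj = bf.random_graph(n, rng.uniform(0.2, 0.8), rng)
            net = _net(adj)
            glob, nodal = hd.all_metrics(net)
            assert glob.E_glob == hd.global_efficiency(net)
            assert np.array_equal(nodal.degree, hd.degree_centrality(net))
            assert np.array_equal(nodal.clustering, hd.nodal_clustering(net))
            assert np.array_equal(nodal.betweenness, hd.betweenness_centrality(net))
            assert np.array_equal(nodal.local_efficiency, hd.local_efficiency(net))


@st.composite
def graphs(draw, max_n=10):
    n = draw(st.integers(3, max_n))
    bits = draw(st.lists(st.booleans(), min_size=n * (n - 1) // 2,
                         max_size=n * (n - 1) // 2))
    a = np.zeros((n, n), dtype=np.int8)
    idx = 0
    for i in range(n):
        for j in range(i + 1, n):
            a[i, j] = a[j, i] = int(bits[idx])
            idx += 1
    return a


class TestProperties:
    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(graphs())
    def test_bounds_and_handshake(self, adj):
        net = _net(adj)
        glob, nodal = hd.all_metrics(net)
        n = adj.shape[0]
        assert nodal.degree.sum() == 2 * net.n_edges
        assert np.all((0 <= nodal.clustering) & (nodal.clustering <= 1))
        assert np.all((0 <= nodal.local_efficiency) & (nodal.local_efficiency <= 1))
        assert np.all(nodal.betweenness >= 0)
        assert np.all(nodal.betweenness <= (n - 1) * (n - 2) / 2 + 1e-9)
        assert 0 <= glob.E_glob <= 1
        assert 0 <= glob.C <= 1
        if glob.connected_pair_fraction > 0:
            assert glob.L >= 1.0

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(graphs(max_n=8), st.randoms(use_true_random=False))
    def test_adding_an_edge_helps(self, adj, rnd):
        n = adj.shape[0]
        missing = [(i, j) for i in range(n) for j in range(i + 1, n)
                   if not adj[i, j]]
        if not missing:
            return
        i, j = rnd.choice(missing)
        before_d = hd.shortest_path_lengths(_net(adj))
        before_e = hd.global_efficiency(_net(adj))
        adj2 = adj.copy()
        adj2[i, j] = adj2[j, i] = 1
        after_d = hd.shortest_path_lengths(_net(adj2))
        assert hd.global_efficiency(_net(adj2)) >= before_e - 1e-12
        assert np.all(after_d <= before_d + 1e-12)

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(graphs(max_n=9), st.integers(0, 10_000))
    def test_permutation_equivariance(self, adj, seed):
        n = adj.shape[0]
        perm = np.random.default_rng(seed).permutation(n)
        glob, nodal = hd.all_metrics(_net(adj))
        glob_p, nodal_p = hd.all_metrics(_net(adj[np.ix_(perm, perm)]))
        if glob.connected_pair_fraction > 0:
            assert glob_p.L == pytest.approx(glob.L, rel=1e-12)
        assert glob_p.E_glob == pytest.approx(glob.E_glob, rel=1e-12)
        assert glob_p.C == pytest.approx(glob.C, rel=1e-12)
        for name in hd.NODAL_METRIC_NAMES:
            assert nodal_p.get(name) == pytest.approx(
                nodal.get(name)[perm], rel=1e-12, abs=1e-12)
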