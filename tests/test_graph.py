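import itertools
import math

import networkx as nx
import numpy as np
import pytest

from apnet.graph_metrics import (
    AdjacencyMatrix,
    clustering_global,
    metrics_for_sweep,
    path_length_global,
    random_reference,
    small_world,
    spanning_tree_backbone,
    surrogate_graphs,
    threshold_sweep,
)
from apnet.spectral_connectivity import ConnectivityMatrix


def _conn(w, labels=None):
    w = np.asarray(w, dtype=float)
    labels = labels or [f"ch{i}" for i in range(w.shape[0])]
    return ConnectivityMatrix(values=w, channel_labels=labels)


def _random_conn(rng, n):
    w = rng.uniform(0.01, 0.99, (n, n))
    w = np.triu(w, 1)
    w = w + w.T
    return _conn(w)


def _adj_from_edges(n, edges):
    m = np.zeros((n, n), dtype=int)
    for i, j in edges:
        m[i, j] = m[j, i] = 1
    return AdjacencyMatrix(matrix=m)


def brute_clustering(adj):
    """Exhaustive triangle enumeration oracle."""
    m = adj.matrix
    n = adj.n_nodes
    cs = []
    for i in range(n):
        nb = [j for j in range(n) if m[i, j]]
        k = len(nb)
        if k < 2:
            cs.append(0.0)
            continue
        links = sum(m[a, b] for a, b in itertools.combinations(nb, 2))
        cs.append(2 * links / (k * (k - 1)))
    return np.array(cs), float(np.mean(cs))


def brute_path_length(adj):
    """Floyd-Warshall oracle."""
    n = adj.n_nodes
    d = np.where(adj.matrix == 1, 1.0, np.inf)
    np.fill_diagonal(d, 0.0)
    for k in range(n):
        d = np.minimum(d, d[:, k][:, None] + d[k, :][None, :])
    per_node = np.array([d[i, [j for j in range(n) if j != i]].mean()
                         for i in range(n)])
    return per_node, float(per_node.mean())


class TestSpanningTree:
    def test_tree_size_28_nodes(self, rng):
        conn = _random_conn(rng, 28)
        mst = spanning_tree_backbone(conn)
        assert mst.k == 27
        assert mst.density == pytest.approx(27 / 378)
        assert nx.is_connected(mst.graph())

    def test_four_node_toy(self):
        w = np.zeros((4, 4))
        for (i, j, v) in [(0, 1, .9), (0, 2, .8), (1, 2, .85),
                          (0, 3, .1), (1, 3, .2), (2, 3, .3)]:
            w[i, j] = w[j, i] = v
        mst = spanning_tree_backbone(_conn(w))
        assert set(mst.edges()) == {(0, 1), (1, 2), (2, 3)}

    def test_maximizes_total_weight_vs_networkx(self, rng):
        for _ in range(5):
            conn = _random_conn(rng, 10)
            mst = spanning_tree_backbone(conn)
            ours = sum(conn.values[i, j] for i, j in mst.edges())
            g = nx.from_numpy_array(conn.values)
            ref = nx.maximum_spanning_tree(g, weight="weight")
            theirs = sum(d["weight"] for _u, _v, d in ref.edges(data=True))
            assert ours == pytest.approx(theirs, rel=1e-12)

    def test_equal_weights_deterministic(self):
        w = np.ones((6, 6)) * 0.5
        np.fill_diagonal(w, 0.0)
        a = spanning_tree_backbone(_conn(w))
        b = spanning_tree_backbone(_conn(w))
        np.testing.assert_array_equal(a.matrix, b.matrix)
        assert a.k == 5

    def test_nan_rejected(self):
        w = np.zeros((3, 3))
        conn = _conn(w)
        conn.values[0, 1] = conn.values[1, 0] = np.nan
        with pytest.raises(ValueError):
            spanning_tree_backbone(conn)


class TestThresholdSweep:
    def test_density_one_is_complete(self, rng):
        conn = _random_conn(rng, 8)
        nets = threshold_sweep(conn, [1.0])
        assert nets[0].k == 28

    def test_nested_and_monotone(self, rng):
        conn = _random_conn(rng, 15)
        densities = [0.15, 0.3, 0.5, 0.8]
        nets = threshold_sweep(conn, densities)
        ls = []
        for lo, hi in zip(nets, nets[1:]):
            assert np.all(lo.matrix <= hi.matrix)  # nested edge sets
            assert lo.k < hi.k
        for net in nets:
            ls.append(path_length_global(net)[1])
        assert all(b <= a + 1e-12 for a, b in zip(ls, ls[1:]))

    def test_edge_count_rounding(self, rng):
        conn = _random_conn(rng, 15)
        n_pairs = 15 * 14 // 2
        for d, net in zip([0.3, 0.6], threshold_sweep(conn, [0.3, 0.6])):
            assert net.k == math.ceil(d * n_pairs)

    def test_clamping_below_mst_density(self, rng):
        conn = _random_conn(rng, 28)
        with pytest.warns(UserWarning, match="clamped"):
            nets = threshold_sweep(conn, [0.036, 0.079])
        assert nets[0].k == 27  # clamped to the MST
        assert nets[1].k == math.ceil(0.079 * 378)

    def test_invalid_density_grids(self, rng):
        conn = _random_conn(rng, 6)
        with pytest.raises(ValueError):
            threshold_sweep(conn, [0.5, 0.3])
        with pytest.raises(ValueError):
            threshold_sweep(conn, [0.0, 0.5])


class TestMetrics:
    def test_toy_graphs(self):
        k4 = _adj_from_edges(4, itertools.combinations(range(4), 2))
        assert clustering_global(k4)[1] == pytest.approx(1.0)
        assert path_length_global(k4)[1] == pytest.approx(1.0)

        star = _adj_from_edges(5, [(0, i) for i in range(1, 5)])
        assert clustering_global(star)[1] == pytest.approx(0.0)

        five = _adj_from_edges(5, [(0, 1), (1, 2), (0, 2), (2, 3), (3, 4)])
        per, glob = clustering_global(five)
        np.testing.assert_allclose(per, [1, 1, 1 / 3, 0, 0])
        assert glob == pytest.approx(7 / 15)

        p3 = _adj_from_edges(3, [(0, 1), (1, 2)])
        per_l, glob_l = path_length_global(p3)
        np.testing.assert_allclose(per_l, [1.5, 1.0, 1.5])
        assert glob_l == pytest.approx(4 / 3)

        c5 = _adj_from_edges(5, [(i, (i + 1) % 5) for i in range(5)])
        per_c, glob_c = path_length_global(c5)
        np.testing.assert_allclose(per_c, [1.5] * 5)
        assert glob_c == pytest.approx(1.5)

    def test_brute_force_oracles_on_random_graphs(self, rng):
        for _ in range(25):
            n = int(rng.integers(4, 9))
            while True:
                g = nx.gnp_random_graph(n, 0.5, seed=int(rng.integers(1 << 30)))
                if nx.is_connected(g):
                    break
            adj = AdjacencyMatrix(matrix=nx.to_numpy_array(g, dtype=int))
            per_c, c = clustering_global(adj)
            oc_per, oc = brute_clustering(adj)
            np.testing.assert_allclose(per_c, oc_per, atol=1e-12)
            assert c == pytest.approx(oc, abs=1e-12)
            per_l, l = path_length_global(adj)
            ol_per, ol = brute_path_length(adj)
            np.testing.assert_allclose(per_l, ol_per, atol=1e-12)
            assert l == pytest.approx(ol, abs=1e-12)

    def test_disconnected_graph_rejected(self):
        adj = _adj_from_edges(4, [(0, 1), (2, 3)])
        with pytest.raises(ValueError):
            path_length_global(adj)


class TestRandomReference:
    def test_degree_sequences_preserved_exactly(self, rng):
        g = nx.connected_watts_strogatz_graph(20, 4, 0.2, seed=4)
        adj = AdjacencyMatrix(matrix=nx.to_numpy_array(g, dtype=int))
        orig = sorted(d for _n, d in g.degree())
        for sur in surrogate_graphs(adj, 5, seed=rng):
            assert sorted(d for _n, d in sur.graph().degree()) == orig
            assert sur.k == adj.k
            assert nx.is_connected(sur.graph())

    def test_randomizing_random_graph_is_neutral(self, rng):
        # gamma/lambda of a single instance fluctuate; the statistical
        # statement is that they average to 1 over random-graph inputs.
        gammas, lambdas = [], []
        seed = 0
        while len(gammas) < 8:
            g = nx.gnp_random_graph(28, 0.2, seed=seed)
            seed += 1
            if not nx.is_connected(g):
                continue
            adj = AdjacencyMatrix(matrix=nx.to_numpy_array(g, dtype=int))
            _, c = clustering_global(adj)
            _, l = path_length_global(adj)
            c_rand, l_rand = random_reference(adj, n_surrogates=10, seed=rng)
            gammas.append(c / c_rand)
            lambdas.append(l / l_rand)
        assert np.mean(gammas) == pytest.approx(1.0, abs=0.1)
        assert np.mean(lambdas) == pytest.approx(1.0, abs=0.1)

    def test_ring_lattice_is_strongly_clustered(self, rng):
        g = nx.watts_strogatz_graph(28, 4, 0.0, seed=0)  # pure lattice
        adj = AdjacencyMatrix(matrix=nx.to_numpy_array(g, dtype=int))
        _, c = clustering_global(adj)
        assert c == pytest.approx(0.5)  # closed form 3(k-2)/(4(k-1)), k=4
        c_rand, _ = random_reference(adj, n_surrogates=10, seed=rng)
        assert c / c_rand > 2.0

    def test_complete_graph_falls_back(self, rng):
        adj = _adj_from_edges(5, itertools.combinations(range(5), 2))
        with pytest.warns(UserWarning):
            c_rand, l_rand = random_reference(adj, n_surrogates=2, seed=rng)
        assert c_rand == pytest.approx(1.0)
        assert l_rand == pytest.approx(1.0)


class TestSmallWorld:
    def test_ratios(self):
        m = small_world(0.5, 0.25, 2.0, 1.6)
        assert m.gamma == pytest.approx(2.0)
        assert m.lambda_ == pytest.approx(1.25)
        assert m.sigma == pytest.approx(1.6)
        unit = small_world(0.3, 0.3, 1.7, 1.7)
        assert unit.sigma == pytest.approx(1.0)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            small_world(0.0, 0.2, 1.5, 1.5)

    def test_watts_strogatz_is_small_world(self, rng):
        sigmas = []
        for seed in range(5):
            g = nx.connected_watts_strogatz_graph(28, 4, 0.1, seed=seed)
            adj = AdjacencyMatrix(matrix=nx.to_numpy_array(g, dtype=int))
            _, c = clustering_global(adj)
            _, l = path_length_global(adj)
            c_rand, l_rand = random_reference(adj, n_surrogates=8, seed=rng)
            sigmas.append(small_world(c, c_rand, l, l_rand).sigma)
        assert np.mean(sigmas) > 1.0


class TestSweepMetrics:
    def test_metrics_for_sweep_shapes_and_density(self, rng):
        conn = _random_conn(rng, 12)
        out = metrics_for_sweep(conn, [0.3, 0.5], n_surrogates=3, seed=rng)
        assert len(out) == 2
        for m, d in zip(out, [0.3, 0.5]):
            assert m.density == pytest.approx(math.ceil(d * 66) / 66)
            assert m.sigma == pytest.approx(m.gamma / m.lambda_)
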