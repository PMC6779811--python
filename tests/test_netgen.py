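"""Network generation, virtual resection, graph metrics and I/O."""

import itertools

import numpy as np
import pytest

from ictonet.netgen import (GeneratorConfig, Network, generate_network,
                            node_metrics, read_network, remove_nodes,
                            set_average_metric, write_network)


def _random_config(rng):
    topology = rng.choice(["scale_free_ba", "scale_free_static",
                           "random_regular_directed", "random_undirected"])
    n = int(rng.integers(4, 16))
    if topology == "random_regular_directed":
        degree, directed = float(rng.integers(1, 3)), True
    elif topology == "random_undirected":
        degree, directed = float(rng.integers(2, 4)), False
    else:
        degree, directed = float(rng.integers(2, 4)), bool(rng.integers(2))
    return GeneratorConfig(topology, n, degree, gamma=3.0, directed=directed,
                           seed=int(rng.integers(2**31)))


def test_generated_networks_satisfy_invariants():
    """Every generated network is square, finite, nonnegative, loop-free,
    binary, and symmetric when undirected (fuzz over 100 random configs)."""
    rng = np.random.default_rng(5)
    for _ in range(100):
        cfg = _random_config(rng)
        net = generate_network(cfg)
        w = net.weights
        assert w.shape == (cfg.n_nodes, cfg.n_nodes)
        assert np.all(np.isfinite(w)) and np.all(w >= 0)
        assert np.all(np.diag(w) == 0)
        assert set(np.unique(w)) <= {0.0, 1.0}
        if not cfg.directed:
            assert np.array_equal(w, w.T)


def test_generation_is_deterministic_in_seed():
    cfg = GeneratorConfig("scale_free_static", 20, 2.0, 3.0, True, seed=123)
    a = generate_network(cfg).weights
    b = generate_network(cfg).weights
    assert np.array_equal(a, b)
    c = generate_network(GeneratorConfig("scale_free_static", 20, 2.0, 3.0,
                                         True, seed=124)).weights
    assert not np.array_equal(a, c)


def test_regular_digraph_has_exact_constant_degrees():
    """A 20-node digraph with in/out degree 2 has exactly 40 edges and a
    perfectly flat degree sequence."""
    net = generate_network(
        GeneratorConfig("random_regular_directed", 20, 2.0, seed=3))
    assert net.n_edges == 40
    assert np.all(net.weights.sum(axis=0) == 2)
    assert np.all(net.weights.sum(axis=1) == 2)


def test_unsupported_topology_and_infeasible_degree_fail():
    with pytest.raises(ValueError, match="unsupported topology"):
        GeneratorConfig("small_world", 10, 2.0)
    with pytest.raises(ValueError):
        generate_network(
            GeneratorConfig("random_regular_directed", 4, 3.7, seed=0))


def test_static_model_degree_tail_exponent_near_three():
    """Hill maximum-likelihood estimate of the in-degree tail on a pooled
    static-model ensemble is close to the target exponent gamma = 3."""
    degs = []
    for seed in range(3):
        net = generate_network(
            GeneratorConfig("scale_free_static", 1000, 4.0, 3.0, True,
                            seed=seed))
        degs.append(net.weights.sum(axis=0))
    k = np.concatenate(degs)
    kmin = 4.0
    tail = k[k >= kmin]
    alpha = 1.0 + len(tail) / np.sum(np.log(tail / (kmin - 0.5)))
    assert 2.3 < alpha < 3.9


def test_remove_nodes_edge_cases(net12):
    assert np.array_equal(remove_nodes(net12, []).weights, net12.weights)
    assert not np.any(remove_nodes(net12, range(12)).weights)
    with pytest.raises(IndexError):
        remove_nodes(net12, [99])
    # original untouched
    before = net12.weights.copy()
    remove_nodes(net12, [0, 1])
    assert np.array_equal(net12.weights, before)


def test_remove_nodes_chain_disconnects_middle():
    w = np.zeros((3, 3))
    w[0, 1] = w[1, 2] = 1.0
    net = Network(weights=w, directed=True)
    cut = remove_nodes(net, {1})
    assert cut.n_edges == 0


def test_remove_nodes_composes_as_union(net12):
    rng = np.random.default_rng(8)
    for _ in range(20):
        a = set(rng.choice(12, size=rng.integers(0, 5), replace=False).tolist())
        b = set(rng.choice(12, size=rng.integers(0, 5), replace=False).tolist())
        two_step = remove_nodes(remove_nodes(net12, a), b)
        one_step = remove_nodes(net12, a | b)
        assert np.array_equal(two_step.weights, one_step.weights)


# ---------------------------------------------------------------------------
# Graph metrics
# ---------------------------------------------------------------------------


def _brute_betweenness(w):
    """Exhaustive shortest-path betweenness for small unweighted graphs."""
    n = w.shape[0]
    bet = np.zeros(n)
    # all shortest paths by BFS path enumeration
    for s in range(n):
        for t in range(n):
            if s == t:
                continue
            # BFS distances
            import collections
            dist = {s: 0}
            q = collections.deque([s])
            while q:
                u = q.popleft()
                for v in np.nonzero(w[u])[0]:
                    if v not in dist:
                        dist[v] = dist[u] + 1
                        q.append(int(v))
            if t not in dist:
                continue
            # enumerate all shortest paths by DFS along decreasing distance
            paths = []
            stack = [[t]]
            while stack:
                path = stack.pop()
                u = path[-1]
                if u == s:
                    paths.append(path)
                    continue
                for v in np.nonzero(w[:, u])[0]:
                    if dist.get(int(v), -1) == dist[u] - 1:
                        stack.append(path + [int(v)])
            for path in paths:
                for mid in path[1:-1]:
                    bet[mid] += 1.0 / len(paths)
    return bet


def test_metrics_agree_with_bruteforce_on_small_graphs():
    rng = np.random.default_rng(2)
    for _ in range(12):
        n = int(rng.integers(3, 7))
        w = np.triu((rng.random((n, n)) < 0.5).astype(float), 1)
        w = w + w.T
        net = Network(weights=w, directed=False)
        m = node_metrics(net)
        # betweenness vs exhaustive path enumeration (x2: both directions)
        expected = _brute_betweenness(w) / 2.0
        assert np.allclose(m.betweenness, expected)
        # clustering vs triangle-count formula
        for i in range(n):
            neigh = np.nonzero(w[i])[0]
            k = len(neigh)
            if k < 2:
                assert m.clustering[i] == 0
            else:
                tri = sum(w[a, b] for a, b in itertools.combinations(neigh, 2))
                assert m.clustering[i] == pytest.approx(2 * tri / (k * (k - 1)))


def test_path_graph_betweenness():
    w = np.zeros((3, 3))
    w[0, 1] = w[1, 0] = w[1, 2] = w[2, 1] = 1.0
    m = node_metrics(Network(weights=w, directed=False))
    assert m.betweenness[1] == pytest.approx(1.0)
    assert m.betweenness[0] == m.betweenness[2] == 0.0


def test_triangle_clustering_is_one():
    w = 1.0 - np.eye(3)
    m = node_metrics(Network(weights=w, directed=False))
    assert np.allclose(m.clustering, 1.0)


def test_star_hub_has_maximal_eigenvector_centrality():
    n = 6
    w = np.zeros((n, n))
    w[0, 1:] = w[1:, 0] = 1.0
    m = node_metrics(Network(weights=w, directed=False))
    assert np.argmax(m.eigenvector) == 0
    assert m.eigenvector[0] > m.eigenvector[1:].max()


def test_eigenvector_absent_for_directed(net12):
    m = node_metrics(net12)
    assert m.eigenvector is None
    with pytest.raises(ValueError):
        set_average_metric(m, {0, 1}, "eigenvector")


def test_set_average_metric(net12):
    m = node_metrics(net12)
    assert set_average_metric(m, {3}, "degree") == m.degree[3]
    rng = np.random.default_rng(1)
    for _ in range(10):
        x = rng.choice(12, size=rng.integers(1, 6), replace=False).tolist()
        total = sum(m.betweenness[i] for i in x)  # independent accumulation
        assert set_average_metric(m, x, "betweenness") == pytest.approx(
            total / len(x))
    with pytest.raises(ValueError):
        set_average_metric(m, set(), "degree")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("fmt", ["csv-matrix", "edge-list"])
def test_roundtrip(tmp_path, net12, fmt):
    path = tmp_path / "net.csv"
    write_network(net12, path, fmt)
    back = read_network(path, fmt)
    assert np.array_equal(back.weights, net12.weights)
    assert back.directed == net12.directed


def test_roundtrip_preserves_float_weights(tmp_path):
    rng = np.random.default_rng(0)
    w = np.triu(rng.random((5, 5)), 1)
    w = w + w.T
    net = Network(weights=w, directed=False)
    for fmt in ("csv-matrix", "edge-list"):
        path = tmp_path / "x.csv"
        write_network(net, path, fmt)
        assert np.array_equal(read_network(path, fmt).weights, w)


def test_edge_list_rejects_negative_weight(tmp_path):
    path = tmp_path / "bad.csv"
    path.write_text("# n_nodes=3 directed=true\nsource,target,weight\n0,1,-2.0\n")
    with pytest.raises(ValueError, match="negative weight"):
        read_network(path, "edge-list")


def test_empty_edge_list_gives_edgeless_network(tmp_path):
    path = tmp_path / "empty.csv"
    path.write_text("# n_nodes=3 directed=true\nsource,target,weight\n")
    net = read_network(path, "edge-list")
    assert net.n_nodes == 3 and net.n_edges == 0


def test_malformed_line_names_the_line(tmp_path):
    path = tmp_path / "bad.csv"
    path.write_text("# n_nodes=3 directed=true\nsource,target,weight\n0,x,1\n")
    with pytest.raises(ValueError, match="line 3"):
        read_network(path, "edge-list")


def test_network_invariant_violations_rejected():
    with pytest.raises(ValueError):
        Network(weights=np.ones((2, 3)))
    with pytest.raises(ValueError):
        Network(weights=-np.ones((3, 3)))
    with pytest.raises(ValueError):
        Network(weights=np.ones((3, 3)))  # nonzero diagonal
    asym = np.zeros((3, 3))
    asym[0, 1] = 1.0
    with pytest.raises(ValueError):
        Network(weights=asym, directed=False)
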