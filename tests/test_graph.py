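"""Graph metrics against brute-force oracles, nulls, small-worldness."""

import numpy as np
import pytest

from pdcnet import graph


def _random_digraph(rng, n, density=0.5):
    W = rng.uniform(0.1, 1.0, size=(n, n))
    W[rng.uniform(size=(n, n)) > density] = 0.0
    np.fill_diagonal(W, 0.0)
    return W


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------

def _brute_degrees(W):
    n = W.shape[0]
    a = (W > 0).astype(int)
    ind = [sum(W[j, i] for j in range(n)) for i in range(n)]
    outd = [sum(W[i, j] for j in range(n)) for i in range(n)]
    comb = [sum(a[i, j] + a[j, i] for j in range(n)) for i in range(n)]
    bidir = [sum(a[i, j] * a[j, i] for j in range(n)) for i in range(n)]
    return ind, outd, comb, bidir


def _brute_clustering(W):
    n = W.shape[0]
    U = np.cbrt(W / W.max())
    S = U + U.T
    _, _, comb, bidir = _brute_degrees(W)
    cc = np.zeros(n)
    for i in range(n):
        num = 0.0
        for j in range(n):
            for h in range(n):
                num += S[i, j] * S[j, h] * S[h, i]
        den = comb[i] * (comb[i] - 1) - 2 * bidir[i]
        cc[i] = num / (2 * den) if den > 0 else 0.0
    return cc


def _brute_path_length(W):
    n = W.shape[0]
    d = np.full((n, n), np.inf)
    for i in range(n):
        d[i, i] = 0.0
    src, tgt = np.nonzero(W)
    for s, t in zip(src, tgt):
        d[s, t] = 1.0 / W[s, t]
    for k in range(n):  # Floyd-Warshall
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    inv = [1.0 / d[i, j] for i in range(n) for j in range(n) if i != j and np.isfinite(d[i, j])]
    return n * (n - 1) / sum(inv) if inv else float("inf")


def test_metrics_match_brute_force_enumeration():
    rng = np.random.default_rng(12)
    for trial in range(20):
        n = int(rng.integers(3, 8))
        W = _random_digraph(rng, n, density=float(rng.uniform(0.2, 0.9)))
        if np.count_nonzero(W) == 0:
            continue
        m = graph.degrees(W)
        ind, outd, comb, bidir = _brute_degrees(W)
        np.testing.assert_allclose(m.in_degree, ind, atol=1e-12)
        np.testing.assert_allclose(m.out_degree, outd, atol=1e-12)
        np.testing.assert_array_equal(m.comb_degree, comb)
        np.testing.assert_array_equal(m.bidirectional, bidir)
        cc, mean_cc = graph.clustering(W)
        np.testing.assert_allclose(cc, _brute_clustering(W), atol=1e-10)
        assert mean_cc == pytest.approx(np.mean(cc))
        assert graph.path_length(W) == pytest.approx(_brute_path_length(W))


def test_complete_uniform_digraph_clustering_is_one():
    n = 4
    W = np.ones((n, n)) - np.eye(n)
    cc, mean_cc = graph.clustering(W)
    np.testing.assert_allclose(cc, 1.0, atol=1e-12)
    assert mean_cc == pytest.approx(1.0)


def test_clustering_bounds_and_binary_equivalence(rng):
    W = _random_digraph(np.random.default_rng(5), 6, 0.6)
    cc, _ = graph.clustering(W)
    assert np.all((cc >= 0) & (cc <= 1 + 1e-12))
    # equal weights reduce to the binary directed clustering
    B = (W > 0).astype(float)
    cc_w, _ = graph.clustering(B * 0.37)
    cc_b, _ = graph.clustering(B)
    np.testing.assert_allclose(cc_w, cc_b, atol=1e-12)


def test_path_length_disconnection_convention():
    W = np.zeros((3, 3))
    W[0, 1] = 2.0  # single edge: only pair (0,1) reachable, d = 0.5
    assert graph.path_length(W) == pytest.approx(3 * 2 / (1 / 0.5))
    assert graph.path_length(np.zeros((3, 3))) == float("inf")


def test_connection_strength_is_twice_total_weight(rng):
    W = _random_digraph(np.random.default_rng(8), 5)
    assert graph.connection_strength(W) == pytest.approx(2.0 * W.sum())


# ---------------------------------------------------------------------------
# cost thresholding
# ---------------------------------------------------------------------------

def test_threshold_edge_count():
    rng = np.random.default_rng(3)
    W = rng.uniform(0.01, 1.0, size=(10, 10))
    np.fill_diagonal(W, 0.0)
    for cost in (0.05, 0.1, 0.2, 0.3):
        gt = graph.threshold_at_cost(W, cost)
        assert gt.n_edges == int(np.floor(cost * 90 + 1e-9))
        kept = gt.W[gt.W > 0]
        assert kept.min() >= np.sort(W[W > 0])[::-1][gt.n_edges - 1]


def test_threshold_tie_break_deterministic():
    W = np.ones((4, 4)) - np.eye(4)  # all weights tie
    gt = graph.threshold_at_cost(W, 0.25)  # keep floor(0.25*12) = 3 edges
    src, tgt = np.nonzero(gt.W)
    assert list(zip(src, tgt)) == [(0, 1), (0, 2), (0, 3)]


def test_threshold_rejects_bad_cost():
    with pytest.raises(ValueError):
        graph.threshold_at_cost(np.zeros((3, 3)), 0.0)


def test_default_cost_sweep():
    costs = graph.default_costs()
    assert len(costs) == 26
    assert costs[0] == 0.05 and costs[-1] == 0.30


# ---------------------------------------------------------------------------
# degree-preserving nulls
# ---------------------------------------------------------------------------

def test_nulls_preserve_weighted_out_degrees():
    rng = np.random.default_rng(21)
    W = _random_digraph(rng, 12, 0.4)
    nulls = graph.random_nulls(W, n=25, seed=2)
    assert len(nulls) == 25
    for g in nulls:
        Wn = g.W
        assert np.all(np.diag(Wn) == 0)
        # per-node weighted out-degree and out-edge count preserved exactly
        np.testing.assert_allclose(Wn.sum(axis=1), W.sum(axis=1), atol=1e-12)
        np.testing.assert_array_equal(
            (Wn > 0).sum(axis=1), (W > 0).sum(axis=1)
        )
        # each node's multiset of outgoing weights is preserved
        for i in range(W.shape[0]):
            np.testing.assert_allclose(
                np.sort(Wn[i][Wn[i] > 0]), np.sort(W[i][W[i] > 0]), atol=1e-12
            )


def test_combinatorial_nulls_preserve_counts_and_pool():
    rng = np.random.default_rng(22)
    W = _random_digraph(rng, 10, 0.4)
    for g in graph.random_nulls(W, n=10, seed=3, mode="combinatorial"):
        np.testing.assert_array_equal((g.W > 0).sum(axis=1), (W > 0).sum(axis=1))
        np.testing.assert_allclose(
            np.sort(g.W[g.W > 0]), np.sort(W[W > 0]), atol=1e-12
        )


def test_nulls_reject_empty_graph():
    with pytest.raises(ValueError):
        graph.random_nulls(np.zeros((4, 4)), n=2)


# ---------------------------------------------------------------------------
# small-worldness
# ---------------------------------------------------------------------------

def test_sigma_near_one_for_random_graph():
    rng = np.random.default_rng(30)
    W = rng.uniform(0.01, 1.0, size=(30, 30))
    np.fill_diagonal(W, 0.0)
    res = graph.small_world(W, costs=np.array([0.2]), n_null=50, seed=1)
    assert abs(float(res.sigma[0]) - 1.0) < 0.1


def test_gamma_above_one_for_ring_lattice():
    n, k = 30, 4  # each node connects to k forward and k backward neighbors
    W = np.zeros((n, n))
    for i in range(n):
        for d in range(1, k + 1):
            W[i, (i + d) % n] = 1.0
            W[i, (i - d) % n] = 1.0
    cost = (2 * k) / (n - 1)  # keep every lattice edge
    res = graph.small_world(W, costs=np.array([cost]), n_null=50, seed=2)
    assert float(res.gamma[0]) > 1.0
    assert float(res.sigma[0]) > 1.0


def test_small_world_frame_columns():
    rng = np.random.default_rng(9)
    W = _random_digraph(rng, 12, 0.8)
    res = graph.small_world(W, costs=np.array([0.1, 0.2]), n_null=10, seed=0)
    frame = res.to_frame()
    assert list(frame["cost"]) == [0.1, 0.2]
    for col in ("C", "L", "gamma", "lambda", "sigma"):
        assert col in frame.columns


def test_networkx_roundtrip():
    W = np.array([[0.0, 0.5, 0.0], [0.0, 0.0, 1.5], [0.2, 0.0, 0.0]])
    g = graph.WeightedDigraph(W=W, layers=("pcl", "gcl", "other"))
    G = graph.to_networkx(g)
    assert G.number_of_edges() == 3
    assert G[1][2]["weight"] == 1.5
    assert G.nodes[0]["layer"] == "pcl"
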