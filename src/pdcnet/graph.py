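"""Weighted directed graph characteristics and cost-matched small-world analysis.

Nodes are recording sites (neural populations), edges the causal interactions
estimated by the connectivity stage; weights are association-matrix entries.

Metrics
-------
* weighted in-/out-degree (column/row sums of W) and the network connection
  strength (sum of all node degrees = twice the total edge weight);
* the Fagiolo weighted directed clustering coefficient, built from the
  elementwise cube root of the max-normalized weight matrix;
* characteristic path length as the harmonic mean of directed shortest-path
  lengths with edge length = 1/weight (unreachable pairs contribute zero);
* small-worldness sigma = gamma / lambda, where gamma and lambda normalize
  clustering and path length by their means over out-degree-preserving random
  networks, compared across conditions at matched cost (edge density), with
  cost swept from 0.05 to 0.30 in steps of 0.01 by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import shortest_path as _csgraph_shortest_path

__all__ = [
    "WeightedDigraph",
    "NodeMetrics",
    "SmallWorldResult",
    "degrees",
    "connection_strength",
    "clustering",
    "path_length",
    "threshold_at_cost",
    "random_nulls",
    "small_world",
    "default_costs",
    "to_networkx",
    "write_graphml",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WeightedDigraph:
    """Nonnegative weight matrix with zero diagonal plus optional labels."""

    W: np.ndarray
    labels: tuple | None = None
    layers: tuple | None = None

    def __post_init__(self) -> None:
        W = np.asarray(self.W, dtype=float)
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ValueError("W must be square")
        if np.any(W < 0):
            raise ValueError("weights must be nonnegative")
        if np.any(np.diag(W) != 0):
            raise ValueError("self-loops are not allowed")
        object.__setattr__(self, "W", W)

    @property
    def n_nodes(self) -> int:
        return self.W.shape[0]

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(self.W))


@dataclass(frozen=True)
class NodeMetrics:
    in_degree: np.ndarray       # weighted
    out_degree: np.ndarray      # weighted
    comb_degree: np.ndarray     # combinatorial (edge count, in + out)
    bidirectional: np.ndarray   # reciprocated-edge count per node
    clustering: np.ndarray | None = None


@dataclass(frozen=True)
class SmallWorldResult:
    """Per-cost clustering/path-length ratios against the random baseline."""

    costs: np.ndarray
    C: np.ndarray
    L: np.ndarray
    C_rand: np.ndarray
    L_rand: np.ndarray
    gamma: np.ndarray
    lam: np.ndarray
    sigma: np.ndarray
    n_null: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cost": self.costs,
                "C": self.C,
                "L": self.L,
                "C_r": self.C_rand,
                "L_r": self.L_rand,
                "gamma": self.gamma,
                "lambda": self.lam,
                "sigma": self.sigma,
            }
        )


def _as_matrix(g) -> np.ndarray:
    if isinstance(g, WeightedDigraph):
        return g.W
    return WeightedDigraph(W=np.asarray(g, dtype=float)).W


# ---------------------------------------------------------------------------
# node metrics
# ---------------------------------------------------------------------------

def degrees(g) -> NodeMetrics:
    """Weighted in-/out-degrees plus the combinatorial counts.

    ``out_i = sum_j W[i, j]`` (edges originating at i) and
    ``in_i = sum_j W[j, i]`` (edges pointing at i); the combinatorial degree
    counts the edges touching a node in either direction and the
    bidirectional count the reciprocated pairs, both used by the clustering
    denominator.
    """
    W = _as_matrix(g)
    a = (W > 0).astype(int)
    return NodeMetrics(
        in_degree=W.sum(axis=0),
        out_degree=W.sum(axis=1),
        comb_degree=a.sum(axis=0) + a.sum(axis=1),
        bidirectional=(a * a.T).sum(axis=1),
    )


def connection_strength(g) -> float:
    """Sum of all node degrees: ``sum_i (in_i + out_i) = 2 * sum W``."""
    return float(2.0 * _as_matrix(g).sum())


def clustering(g) -> tuple[np.ndarray, float]:
    """Fagiolo's weighted directed clustering coefficient per node.

    Weights are first normalized by the maximum weight so all lie in [0, 1];
    with ``U`` the elementwise cube root of the normalized matrix,

        CC_i = [(U + U^T)^3]_ii / (2 * [k_i (k_i - 1) - 2 k_i^bidir]),

    where ``k_i`` is the combinatorial degree and ``k_i^bidir`` the number of
    reciprocated partners.  Nodes with a zero denominator get CC_i = 0.
    Returns (per-node CC, network mean CC over all nodes).
    """
    W = _as_matrix(g)
    wmax = W.max()
    if wmax == 0:
        cc = np.zeros(W.shape[0])
        return cc, 0.0
    U = np.cbrt(W / wmax)
    S = U + U.T
    num = np.einsum("ij,jk,ki->i", S, S, S) / 2.0
    m = degrees(W)
    den = m.comb_degree * (m.comb_degree - 1) - 2 * m.bidirectional
    cc = np.where(den > 0, num / np.where(den > 0, den, 1), 0.0)
    return cc, float(cc.mean())


def path_length(g) -> float:
    """Harmonic-mean characteristic path length with edge length 1/weight.

    ``L = N(N-1) / sum_{i != j} 1/d_ij`` where ``d_ij`` is the directed
    shortest-path length; unreachable pairs contribute 0 to the sum.  Returns
    ``inf`` when no ordered pair is reachable.
    """
    W = _as_matrix(g)
    n = W.shape[0]
    if n < 2:
        return float("inf")
    with np.errstate(divide="ignore"):
        lengths = np.where(W > 0, 1.0 / W, 0.0)
    d = _csgraph_shortest_path(lengths, method="D", directed=True)
    np.fill_diagonal(d, np.inf)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(d), 1.0 / d, 0.0)
    total = inv.sum()
    if total == 0:
        return float("inf")
    return float(n * (n - 1) / total)


# ---------------------------------------------------------------------------
# cost thresholding
# ---------------------------------------------------------------------------

def default_costs() -> np.ndarray:
    """The standard cost sweep: 0.05 to 0.30 in steps of 0.01 (26 points)."""
    return np.round(np.arange(5, 31) * 0.01, 2)


def threshold_at_cost(g, cost: float) -> WeightedDigraph:
    """Keep only the ``floor(cost * N(N-1))`` largest-weight directed edges.

    Cost is edge density: edges kept over the maximum possible ``N(N-1)``.
    Retained edges keep their weights; ties break deterministically by
    (weight descending, source ascending, target ascending).
    """
    if not 0 < cost <= 1:
        raise ValueError("cost must be in (0, 1]")
    W = _as_matrix(g)
    n = W.shape[0]
    m = int(np.floor(cost * n * (n - 1) + 1e-9))
    src, tgt = np.nonzero(W)
    order = sorted(range(len(src)), key=lambda k: (-W[src[k], tgt[k]], src[k], tgt[k]))
    keep = order[:m]
    out = np.zeros_like(W)
    out[src[keep], tgt[keep]] = W[src[keep], tgt[keep]]
    layers = g.layers if isinstance(g, WeightedDigraph) else None
    labels = g.labels if isinstance(g, WeightedDigraph) else None
    return WeightedDigraph(W=out, labels=labels, layers=layers)


# ---------------------------------------------------------------------------
# degree-preserving random nulls
# ---------------------------------------------------------------------------

def random_nulls(
    g,
    n: int = 100,
    seed: int = 0,
    mode: str = "weighted",
) -> list[WeightedDigraph]:
    """Random directed networks preserving each node's out-degree.

    Every null keeps the node count, edge count and per-node out-degree
    sequence.  In ``mode='weighted'`` (default) each node also keeps its own
    outgoing weights — the weights travel with their source — while the
    targets are redrawn uniformly at random among the other nodes (no
    self-loops, no duplicate edges).  ``mode='combinatorial'`` additionally
    shuffles the global weight pool across all edges, preserving only the
    out-edge counts per node.  Deterministic given ``seed``.
    """
    W = _as_matrix(g)
    nn = W.shape[0]
    if np.count_nonzero(W) == 0:
        raise ValueError("cannot rewire a graph with no edges")
    rng = np.random.default_rng(seed)
    out_lists = [np.sort(W[i, np.nonzero(W[i])[0]])[::-1] for i in range(nn)]
    nulls = []
    for _ in range(n):
        Wn = np.zeros_like(W)
        for i in range(nn):
            w = out_lists[i]
            if w.size == 0:
                continue
            others = np.delete(np.arange(nn), i)
            targets = rng.choice(others, size=w.size, replace=False)
            Wn[i, targets] = rng.permutation(w)
        if mode == "combinatorial":
            src, tgt = np.nonzero(Wn)
            Wn[src, tgt] = rng.permutation(Wn[src, tgt])
        elif mode != "weighted":
            raise ValueError(f"unknown null mode {mode!r}")
        nulls.append(WeightedDigraph(W=Wn))
    return nulls


# ---------------------------------------------------------------------------
# small-world analysis
# ---------------------------------------------------------------------------

def small_world(
    g,
    costs: np.ndarray | None = None,
    n_null: int = 100,
    seed: int = 0,
    null_mode: str = "weighted",
) -> SmallWorldResult:
    """Cost-matched small-worldness against out-degree-preserving nulls.

    At each cost the graph is thresholded to that edge density; its mean
    clustering C and characteristic path length L are compared with the means
    C_r, L_r over ``n_null`` random networks of the thresholded graph:
    gamma = C/C_r, lambda = L/L_r, sigma = gamma/lambda.  Where the nulls are
    disconnected (infinite L_r) the ratios are reported as NaN (missing).
    """
    if costs is None:
        costs = default_costs()
    costs = np.asarray(costs, dtype=float)
    nc = len(costs)
    C = np.empty(nc)
    L = np.empty(nc)
    Cr = np.empty(nc)
    Lr = np.empty(nc)
    ss = np.random.SeedSequence(seed)
    child = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(nc)]
    for k, cost in enumerate(costs):
        gt = threshold_at_cost(g, cost)
        _, C[k] = clustering(gt)
        L[k] = path_length(gt)
        if gt.n_edges == 0:
            Cr[k] = Lr[k] = np.nan
            continue
        nulls = random_nulls(gt, n=n_null, seed=child[k], mode=null_mode)
        Cr[k] = float(np.mean([clustering(x)[1] for x in nulls]))
        Lr[k] = float(np.mean([path_length(x) for x in nulls]))
    with np.errstate(divide="ignore", invalid="ignore"):
        gamma = np.where(Cr > 0, C / Cr, np.nan)
        lam = np.where(np.isfinite(Lr) & (Lr > 0) & np.isfinite(L), L / Lr, np.nan)
        sigma = gamma / lam
    return SmallWorldResult(
        costs=costs, C=C, L=L, C_rand=Cr, L_rand=Lr,
        gamma=gamma, lam=lam, sigma=sigma, n_null=n_null,
    )


# ---------------------------------------------------------------------------
# import/export
# ---------------------------------------------------------------------------

def to_networkx(g):
    """Convert to a ``networkx.DiGraph`` with weight attributes."""
    import networkx as nx

    W = _as_matrix(g)
    G = nx.DiGraph()
    G.add_nodes_from(range(W.shape[0]))
    src, tgt = np.nonzero(W)
    G.add_weighted_edges_from(
        (int(s), int(t), float(W[s, t])) for s, t in zip(src, tgt)
    )
    if isinstance(g, WeightedDigraph) and g.layers is not None:
        for i, layer in enumerate(g.layers):
            G.nodes[i]["layer"] = layer
    return G


def write_graphml(path, g) -> None:
    import networkx as nx

    nx.write_graphml(to_networkx(g), path)


def write_edgelist_csv(path, g) -> None:
    W = _as_matrix(g)
    src, tgt = np.nonzero(W)
    pd.DataFrame(
        {"source": src, "target": tgt, "weight": W[src, tgt]}
    ).to_csv(path, index=False)
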