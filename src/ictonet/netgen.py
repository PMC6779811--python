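"""Weighted-network containers, artificial topologies, graph metrics and I/O.

Networks are the substrate of the whole framework: a node stands for a
recording channel (or an abstract unit in artificial ensembles) and the
entry ``a[i, j]`` is the weight of the directed edge *from* node ``i``
*to* node ``j``.  Artificial ensembles use binary weights; functional
networks inferred from signals are real-weighted.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Iterable

import networkx as nx
import numpy as np

__all__ = [
    "Network",
    "GeneratorConfig",
    "NodeMetrics",
    "generate_network",
    "remove_nodes",
    "node_metrics",
    "set_average_metric",
    "read_network",
    "write_network",
]

TOPOLOGIES = (
    "scale_free_ba",
    "scale_free_static",
    "random_regular_directed",
    "random_undirected",
)


@dataclass(frozen=True)
class Network:
    """A weighted network with ordered node labels.

    ``weights[i, j]`` is the weight of the edge from node ``i`` to node
    ``j``; the matrix is square, nonnegative, finite, with zero diagonal,
    and symmetric when ``directed`` is False.
    """

    weights: np.ndarray
    directed: bool = True
    node_labels: tuple = ()

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError(f"adjacency must be square, got shape {w.shape}")
        if not np.all(np.isfinite(w)):
            raise ValueError("adjacency contains non-finite entries")
        if np.any(w < 0):
            raise ValueError("adjacency contains negative weights")
        if np.any(np.diag(w) != 0):
            raise ValueError("self-loops are not allowed (nonzero diagonal)")
        if not self.directed and not np.allclose(w, w.T):
            raise ValueError("undirected network requires a symmetric matrix")
        labels = tuple(self.node_labels) or tuple(range(w.shape[0]))
        if len(labels) != w.shape[0]:
            raise ValueError("node_labels length does not match matrix size")
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "node_labels", labels)

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @property
    def n_edges(self) -> int:
        nz = int(np.count_nonzero(self.weights))
        return nz if self.directed else nz // 2

    def to_networkx(self):
        cls = nx.DiGraph if self.directed else nx.Graph
        g = cls()
        g.add_nodes_from(range(self.n_nodes))
        src, dst = np.nonzero(self.weights)
        for i, j in zip(src.tolist(), dst.tolist()):
            if not self.directed and i > j:
                continue
            g.add_edge(i, j, weight=float(self.weights[i, j]))
        return g


@dataclass(frozen=True)
class GeneratorConfig:
    topology: str
    n_nodes: int
    mean_degree: float
    gamma: float = 3.0
    directed: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.topology not in TOPOLOGIES:
            raise ValueError(
                f"unsupported topology {self.topology!r}; choose from {TOPOLOGIES}"
            )
        if self.n_nodes < 3:
            raise ValueError("n_nodes must be >= 3")
        if not (0 < self.mean_degree < self.n_nodes):
            raise ValueError("mean_degree must lie in (0, n_nodes)")
        if self.topology.startswith("scale_free") and self.gamma <= 2:
            raise ValueError("scale-free topologies require gamma > 2")


@dataclass
class NodeMetrics:
    """Per-node graph measures; eigenvector centrality only for undirected nets."""

    degree: np.ndarray
    in_degree: np.ndarray
    out_degree: np.ndarray
    betweenness: np.ndarray
    clustering: np.ndarray
    eigenvector: np.ndarray | None = None
    directed: bool = True
    names: tuple = field(default_factory=tuple)

    def get(self, which: str) -> np.ndarray:
        table = {
            "degree": self.degree,
            "in_degree": self.in_degree,
            "out_degree": self.out_degree,
            "betweenness": self.betweenness,
            "clustering": self.clustering,
            "eigenvector": self.eigenvector,
        }
        if which not in table:
            raise KeyError(f"unknown metric {which!r}")
        val = table[which]
        if val is None:
            raise ValueError(
                "eigenvector centrality is undefined for directed networks"
            )
        return val


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------


def _static_model(n: int, mean_degree: float, gamma: float, directed: bool,
                  rng: np.random.Generator) -> np.ndarray:
    # Static scale-free model: node i carries weight i^{-alpha},
    # alpha = 1/(gamma-1); endpoints of each edge drawn independently from
    # the normalized weights until the target edge count is reached.
    alpha = 1.0 / (gamma - 1.0)
    p = (np.arange(1, n + 1, dtype=float)) ** (-alpha)
    p /= p.sum()
    m_target = int(round(n * mean_degree)) if directed else int(round(n * mean_degree / 2))
    max_possible = n * (n - 1) if directed else n * (n - 1) // 2
    if m_target > max_possible:
        raise ValueError("requested mean_degree is infeasible for this n_nodes")
    w = np.zeros((n, n))
    n_edges = 0
    attempts = 0
    cap = 1000 * m_target + 10000
    while n_edges < m_target:
        attempts += 1
        if attempts > cap:
            raise RuntimeError("static-model generation failed to place edges")
        i = rng.choice(n, p=p)
        j = rng.choice(n, p=p)
        if i == j or w[i, j]:
            continue
        w[i, j] = 1.0
        if not directed:
            w[j, i] = 1.0
        n_edges += 1
    return w


def _ba_model(n: int, mean_degree: float, directed: bool,
              rng: np.random.Generator) -> np.ndarray:
    m = max(1, int(round(mean_degree / 2)))
    if not directed:
        g = nx.barabasi_albert_graph(n, m, seed=int(rng.integers(2**31)))
        w = nx.to_numpy_array(g, nodelist=range(n))
        w[w > 0] = 1.0
        return w
    # Directed preferential attachment: each new node sends m out-edges to
    # targets chosen with probability proportional to (in-degree + 1).
    w = np.zeros((n, n))
    for v in range(m, n):
        indeg = w[:, :v].sum(axis=0)[:v] if v else np.array([])
        probs = (indeg + 1.0)
        probs /= probs.sum()
        targets: set[int] = set()
        while len(targets) < min(m, v):
            targets.add(int(rng.choice(v, p=probs)))
        for t in targets:
            w[v, t] = 1.0
    return w


def _random_regular_directed(n: int, d: int, rng: np.random.Generator) -> np.ndarray:
    # Configuration-model pairing of n*d out-stubs with n*d in-stubs,
    # rejecting pairings that contain self-loops or multi-edges.
    if d != int(d) or d < 1 or d >= n:
        raise ValueError(f"in/out degree {d} not realizable for n={n}")
    out_stubs = np.repeat(np.arange(n), d)
    for _ in range(10000):
        perm = rng.permutation(n * d)
        dst = np.repeat(np.arange(n), d)[perm]
        if np.any(out_stubs == dst):
            continue
        pairs = set(zip(out_stubs.tolist(), dst.tolist()))
        if len(pairs) < n * d:
            continue
        w = np.zeros((n, n))
        w[out_stubs, dst] = 1.0
        return w
    raise RuntimeError("failed to realize a regular digraph (too many rejections)")


def _random_undirected(n: int, mean_degree: float, rng: np.random.Generator) -> np.ndarray:
    m = int(round(n * mean_degree / 2))
    if m > n * (n - 1) // 2:
        raise ValueError("mean_degree infeasible")
    g = nx.gnm_random_graph(n, m, seed=int(rng.integers(2**31)))
    w = nx.to_numpy_array(g, nodelist=range(n))
    w[w > 0] = 1.0
    return w


def generate_network(config: GeneratorConfig) -> Network:
    """Generate a binary artificial network of the requested topology.

    Deterministic for a fixed ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_nodes
    if config.topology == "scale_free_static":
        w = _static_model(n, config.mean_degree, config.gamma, config.directed, rng)
    elif config.topology == "scale_free_ba":
        w = _ba_model(n, config.mean_degree, config.directed, rng)
    elif config.topology == "random_regular_directed":
        if not config.directed:
            raise ValueError("random_regular_directed requires directed=True")
        w = _random_regular_directed(n, int(round(config.mean_degree)), rng)
    else:  # random_undirected
        if config.directed:
            raise ValueError("random_undirected requires directed=False")
        w = _random_undirected(n, config.mean_degree, rng)
    return Network(weights=w, directed=config.directed)


# ---------------------------------------------------------------------------
# Virtual resection
# ---------------------------------------------------------------------------


def remove_nodes(net: Network, x: Iterable[int]) -> Network:
    """Virtual resection: zero every incoming and outgoing connection of ``x``.

    The node set stays the same size — removed nodes are disconnected, not
    deleted — so perturbed and unperturbed networks remain comparable.
    """
    idx = sorted(set(int(i) for i in x))
    for i in idx:
        if not (0 <= i < net.n_nodes):
            raise IndexError(f"node index {i} out of range for N={net.n_nodes}")
    w = net.weights.copy()
    if idx:
        w[idx, :] = 0.0
        w[:, idx] = 0.0
    return Network(weights=w, directed=net.directed, node_labels=net.node_labels)


# ---------------------------------------------------------------------------
# Graph metrics
# ---------------------------------------------------------------------------


def _eigenvector_power(w_sym: np.ndarray, tol: float = 1e-10,
                       max_iter: int = 10_000) -> np.ndarray:
    n = w_sym.shape[0]
    if not np.any(w_sym):
        raise ValueError("eigenvector centrality undefined on an edgeless network")
    v = np.full(n, 1.0 / np.sqrt(n))
    # diagonal shift makes the dominant eigenvalue simple on bipartite graphs
    shift = w_sym.sum(axis=1).max()
    for _ in range(max_iter):
        nv = w_sym @ v + shift * v
        norm = np.linalg.norm(nv)
        if norm == 0:
            raise ValueError("power iteration collapsed to zero vector")
        nv /= norm
        if np.linalg.norm(nv - v) < tol:
            return np.abs(nv)
        v = nv
    raise RuntimeError("eigenvector centrality power iteration did not converge")


def node_metrics(net: Network) -> NodeMetrics:
    """Degree, betweenness, clustering and (undirected) eigenvector centrality.

    Betweenness on weighted networks converts affinity weights to distances
    via ``1/weight``.  Clustering on directed networks uses the directed
    generalization implemented by networkx for DiGraphs.
    """
    w = net.weights
    in_deg = w.sum(axis=0)
    out_deg = w.sum(axis=1)
    total = in_deg + out_deg if net.directed else out_deg
    g = net.to_networkx()
    for _, _, data in g.edges(data=True):
        data["distance"] = 1.0 / data["weight"]
    bet = nx.betweenness_centrality(g, weight="distance", normalized=False)
    clus = nx.clustering(g, weight=None)
    eig = None
    if not net.directed and np.any(w):
        eig = _eigenvector_power(w)
    n = net.n_nodes
    return NodeMetrics(
        degree=np.asarray(total, float),
        in_degree=np.asarray(in_deg, float),
        out_degree=np.asarray(out_deg, float),
        betweenness=np.array([bet[i] for i in range(n)], float),
        clustering=np.array([clus[i] for i in range(n)], float),
        eigenvector=eig,
        directed=net.directed,
    )


def set_average_metric(metrics: NodeMetrics, x: Iterable[int], which: str) -> float:
    idx = sorted(set(int(i) for i in x))
    if not idx:
        raise ValueError("set_average_metric requires a nonempty node set")
    vals = metrics.get(which)
    return float(np.mean(vals[idx]))


# ---------------------------------------------------------------------------
# I/O — CSV adjacency matrix and 0-based edge list
# ---------------------------------------------------------------------------


def write_network(net: Network, path, fmt: str = "csv-matrix") -> None:
    if fmt == "csv-matrix":
        with open(path, "w", newline="") as fh:
            wr = csv.writer(fh)
            wr.writerow([f"# directed={net.directed}"])
            wr.writerow(list(net.node_labels))
            for row in net.weights:
                wr.writerow([repr(float(v)) for v in row])
    elif fmt == "edge-list":
        with open(path, "w", newline="") as fh:
            fh.write(f"# n_nodes={net.n_nodes} directed={net.directed}\n")
            fh.write("source,target,weight\n")
            src, dst = np.nonzero(net.weights)
            for i, j in zip(src.tolist(), dst.tolist()):
                if not net.directed and i > j:
                    continue
                fh.write(f"{i},{j},{float(net.weights[i, j])!r}\n")
    else:
        raise ValueError(f"unknown format {fmt!r}")


def _parse_bool(s: str) -> bool:
    return s.strip().lower() in ("true", "1", "yes")


def read_network(path, fmt: str = "csv-matrix") -> Network:
    if fmt == "csv-matrix":
        with open(path, newline="") as fh:
            rows = list(csv.reader(fh))
        directed = True
        if rows and rows[0] and rows[0][0].startswith("# directed="):
            directed = _parse_bool(rows[0][0].split("=", 1)[1])
            rows = rows[1:]
        if not rows:
            raise ValueError(f"{path}: empty adjacency file")
        labels = tuple(rows[0])
        data = []
        for k, row in enumerate(rows[1:], start=2):
            try:
                data.append([float(v) for v in row])
            except ValueError as e:
                raise ValueError(f"{path}: malformed line {k}: {e}") from None
        w = np.asarray(data)
        if w.ndim != 2 or w.shape[0] != w.shape[1] or w.shape[0] != len(labels):
            raise ValueError(f"{path}: non-square adjacency matrix {w.shape}")
        return Network(weights=w, directed=directed, node_labels=labels)
    if fmt == "edge-list":
        with open(path) as fh:
            lines = fh.read().splitlines()
        if not lines or not lines[0].startswith("#"):
            raise ValueError(f"{path}: missing '# n_nodes=... directed=...' header")
        header = dict(tok.split("=") for tok in lines[0][1:].split())
        n = int(header["n_nodes"])
        directed = _parse_bool(header.get("directed", "true"))
        w = np.zeros((n, n))
        start = 2 if len(lines) > 1 and lines[1].startswith("source") else 1
        for k, line in enumerate(lines[start:], start=start + 1):
            if not line.strip():
                continue
            parts = line.split(",")
            try:
                i, j, val = int(parts[0]), int(parts[1]), float(parts[2])
            except (ValueError, IndexError):
                raise ValueError(f"{path}: malformed line {k}: {line!r}") from None
            if val < 0:
                raise ValueError(f"{path}: negative weight on line {k}")
            w[i, j] = val
            if not directed:
                w[j, i] = val
        return Network(weights=w, directed=directed)
    raise ValueError(f"unknown format {fmt!r}")
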