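"""MST-seeded density thresholding and small-world graph metrics.

A weighted connectivity matrix is binarized by first taking the spanning
tree of maximal total connectivity weight ("minimal spanning tree" of the
distance 1 - wPLI), which guarantees a connected network of n-1 edges, and
then adding the strongest remaining edges until the requested edge density
is reached.  Networks along a density sweep are therefore nested.

On each binary network the global clustering coefficient C (mean over
per-node C_i = 2*t_i / (k_i*(k_i-1)), triangles t_i) and the characteristic
path length L (mean over per-node mean shortest-path hop counts) are
computed, then normalized against degree-preserving random references
(Maslov-Sneppen double edge swaps, connectedness enforced):

    gamma = C / C_rand,   lambda = L / L_rand,   sigma = gamma / lambda

sigma >> 1 signals small-world architecture.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np

from apnet.spectral_connectivity import ConnectivityMatrix

__all__ = [
    "AdjacencyMatrix",
    "NetworkMetrics",
    "spanning_tree_backbone",
    "threshold_sweep",
    "clustering_global",
    "path_length_global",
    "random_reference",
    "surrogate_graphs",
    "small_world",
    "metrics_for_sweep",
]


@dataclass
class AdjacencyMatrix:
    """A binary, symmetric, connected network containing the MST backbone."""

    matrix: np.ndarray
    channel_labels: tuple[str, ...] = ()
    band: str = ""
    condition: str = ""
    subject_id: str = ""

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("adjacency matrix must be square")
        if not np.array_equal(m, m.T):
            raise ValueError("adjacency matrix must be symmetric")
        if np.any(np.diag(m) != 0):
            raise ValueError("diagonal must be zero")
        if not np.isin(m, (0, 1)).all():
            raise ValueError("entries must be 0/1")
        self.matrix = m.astype(np.int8)
        if not self.channel_labels:
            self.channel_labels = tuple(f"ch{i}" for i in range(m.shape[0]))

    @property
    def n_nodes(self) -> int:
        return self.matrix.shape[0]

    @property
    def k(self) -> int:
        """Number of edges."""
        return int(self.matrix.sum() // 2)

    @property
    def density(self) -> float:
        n = self.n_nodes
        return self.k / (n * (n - 1) / 2)

    def graph(self) -> nx.Graph:
        return nx.from_numpy_array(self.matrix)

    def edges(self) -> list[tuple[int, int]]:
        iu = np.triu_indices(self.n_nodes, k=1)
        mask = self.matrix[iu] == 1
        return list(zip(iu[0][mask].tolist(), iu[1][mask].tolist()))


@dataclass
class NetworkMetrics:
    """Raw and random-normalized network metrics at one density."""

    C_real: float
    L_real: float
    C_rand: float
    L_rand: float
    density: float
    band: str = ""
    condition: str = ""
    subject_id: str = ""

    @property
    def gamma(self) -> float:
        return self.C_real / self.C_rand

    @property
    def lambda_(self) -> float:
        return self.L_real / self.L_rand

    @property
    def sigma(self) -> float:
        return self.gamma / self.lambda_


def _sorted_edges(conn: ConnectivityMatrix) -> list[tuple[float, int, int]]:
    """All upper-triangle edges ordered by (weight desc, index pair asc)."""
    w = conn.values
    n = w.shape[0]
    edges = [(w[i, j], i, j) for i in range(n) for j in range(i + 1, n)]
    edges.sort(key=lambda e: (-e[0], e[1], e[2]))
    return edges


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[rb] = ra
        return True


def spanning_tree_backbone(conn: ConnectivityMatrix) -> AdjacencyMatrix:
    """Maximum-weight spanning tree of the connectivity matrix.

    Kruskal over edges sorted by (weight desc, node pair asc): the
    deterministic tie-break makes degenerate equal-weight matrices
    reproducible.  Equivalent to the minimal spanning tree of the distance
    1 - wPLI.
    """
    if not np.all(np.isfinite(conn.values)):
        raise ValueError("connectivity matrix contains NaN/Inf")
    n = conn.n_channels
    uf = _UnionFind(n)
    adj = np.zeros((n, n), dtype=np.int8)
    taken = 0
    for _w, i, j in _sorted_edges(conn):
        if uf.union(i, j):
            adj[i, j] = adj[j, i] = 1
            taken += 1
            if taken == n - 1:
                break
    return AdjacencyMatrix(
        matrix=adj,
        channel_labels=conn.channel_labels,
        band=conn.band,
        condition=conn.condition,
        subject_id=conn.subject_id,
    )


def threshold_sweep(
    conn: ConnectivityMatrix, densities: Sequence[float]
) -> list[AdjacencyMatrix]:
    """Nested binary networks: MST plus strongest remaining edges per density.

    Each requested density d yields ceil(d * n(n-1)/2) edges; densities below
    the MST density (n-1 edges) are clamped up to it with a warning.
    """
    densities = list(densities)
    if any(d <= 0 or d > 1 for d in densities):
        raise ValueError("densities must lie in (0, 1]")
    if any(b <= a for a, b in zip(densities, densities[1:])):
        raise ValueError("densities must be strictly increasing")
    n = conn.n_channels
    n_pairs = n * (n - 1) // 2
    mst = spanning_tree_backbone(conn)
    in_net = mst.matrix.astype(bool)
    order = [
        (i, j) for _w, i, j in _sorted_edges(conn) if not in_net[i, j]
    ]
    results = []
    current = mst.matrix.copy()
    k_current = n - 1
    pos = 0
    for d in densities:
        k_target = math.ceil(d * n_pairs)
        if k_target < n - 1:
            warnings.warn(
                f"requested density {d:.4f} below MST density "
                f"{(n - 1) / n_pairs:.4f}; clamped to the MST",
                stacklevel=2,
            )
            k_target = n - 1
        while k_current < k_target and pos < len(order):
            i, j = order[pos]
            pos += 1
            current[i, j] = current[j, i] = 1
            k_current += 1
        results.append(
            AdjacencyMatrix(
                matrix=current.copy(),
                channel_labels=conn.channel_labels,
                band=conn.band,
                condition=conn.condition,
                subject_id=conn.subject_id,
            )
        )
    return results


def clustering_global(adj: AdjacencyMatrix) -> tuple[np.ndarray, float]:
    """Per-node and global clustering coefficient (binary triangles)."""
    cdict = nx.clustering(adj.graph())
    per_node = np.array([cdict[i] for i in range(adj.n_nodes)])
    return per_node, float(per_node.mean())


def path_length_global(adj: AdjacencyMatrix) -> tuple[np.ndarray, float]:
    """Per-node mean shortest-path hop count and its global mean."""
    g = adj.graph()
    if not nx.is_connected(g):
        raise ValueError("network must be connected (MST backbone missing?)")
    n = adj.n_nodes
    per_node = np.empty(n)
    for i, lengths in nx.all_pairs_shortest_path_length(g):
        per_node[i] = sum(lengths[j] for j in lengths if j != i) / (n - 1)
    return per_node, float(per_node.mean())


def random_reference(
    adj: AdjacencyMatrix,
    n_surrogates: int = 50,
    swaps_per_edge: int = 10,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Mean (C_rand, L_rand) over degree-preserving connected surrogates.

    Maslov-Sneppen double edge swaps with connectedness enforced (swaps that
    would disconnect the network are rejected).  Graphs admitting no valid
    swap (complete, or fewer than 4 nodes) fall back to the original with a
    warning.
    """
    if n_surrogates < 1:
        raise ValueError("need at least one surrogate")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n, k = adj.n_nodes, adj.k
    if n < 4 or adj.density >= 1.0:
        warnings.warn(
            "graph too small or dense to rewire; using the original as its "
            "own reference",
            stacklevel=2,
        )
        _, c = clustering_global(adj)
        _, l = path_length_global(adj)
        return c, l
    cs, ls = [], []
    for sur in surrogate_graphs(adj, n_surrogates, swaps_per_edge, rng):
        _, c = clustering_global(sur)
        _, l = path_length_global(sur)
        cs.append(c)
        ls.append(l)
    return float(np.mean(cs)), float(np.mean(ls))


def surrogate_graphs(
    adj: AdjacencyMatrix,
    n_surrogates: int,
    swaps_per_edge: int = 10,
    seed: int | np.random.Generator = 0,
) -> list[AdjacencyMatrix]:
    """Degree-preserving connected surrogates via double edge swaps."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = []
    for _ in range(n_surrogates):
        g = adj.graph()
        try:
            nx.connected_double_edge_swap(g, nswap=swaps_per_edge * adj.k, seed=rng)
        except nx.NetworkXError:
            warnings.warn("edge swap failed; surrogate equals original", stacklevel=2)
        out.append(
            AdjacencyMatrix(
                matrix=nx.to_numpy_array(g, dtype=np.int8),
                channel_labels=adj.channel_labels,
            )
        )
    return out


def small_world(
    C: float,
    C_rand: float,
    L: float,
    L_rand: float,
    density: float = float("nan"),
    **meta: str,
) -> NetworkMetrics:
    """Bundle raw and reference values; gamma/lambda/sigma are derived ratios."""
    for name, v in (("C", C), ("C_rand", C_rand), ("L", L), ("L_rand", L_rand)):
        if not v > 0:
            raise ValueError(f"{name} must be positive, got {v}")
    return NetworkMetrics(
        C_real=C, L_real=L, C_rand=C_rand, L_rand=L_rand, density=density, **meta
    )


def metrics_for_sweep(
    conn: ConnectivityMatrix,
    densities: Sequence[float],
    n_surrogates: int = 50,
    swaps_per_edge: int = 10,
    seed: int | np.random.Generator = 0,
    compute_random: bool = True,
) -> list[NetworkMetrics]:
    """Convenience: threshold sweep then metrics at every density.

    With ``compute_random=False`` the surrogate normalization is skipped and
    C_rand/L_rand are set to 1 (raw C and L analyses only).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = []
    for adj in threshold_sweep(conn, densities):
        _, c = clustering_global(adj)
        _, l = path_length_global(adj)
        if compute_random:
            c_rand, l_rand = random_reference(adj, n_surrogates, swaps_per_edge, rng)
        else:
            c_rand, l_rand = 1.0, 1.0
        out.append(
            NetworkMetrics(
                C_real=c,
                L_real=l,
                C_rand=c_rand,
                L_rand=l_rand,
                density=adj.density,
                band=conn.band,
                condition=conn.condition,
                subject_id=conn.subject_id,
            )
        )
    return out
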