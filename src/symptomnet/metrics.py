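"""Weighted-network distances, shortest paths, and centrality indices.

Edge weights are partial correlations; the travel cost of an edge is the
reciprocal of its absolute weight (strong associations are short), so
geodesics are computed by Dijkstra's algorithm on d_ij = 1/|w_ij|.

Centralities follow the conventions of the psychometric-network literature:

* strength: sum of absolute edge weights at a node;
* expected influence: sum of signed edge weights (distinguishes nodes whose
  ties are protective, i.e. negative, from amplifying ones);
* closeness: reciprocal of the summed geodesic distances to all reachable
  nodes (isolated nodes get 0);
* betweenness: number of node pairs whose selected geodesic passes through
  the node.

Betweenness is integer-valued: exactly one geodesic is selected per
unordered pair, with ties broken toward the lexicographically smallest node
sequence from the smaller-indexed endpoint.  Fractional (Brandes) counting
over all geodesics is available as an option via networkx.
"""

from __future__ import annotations

from dataclasses import dataclass
import heapq

import numpy as np
import pandas as pd

from .ggm import PartialCorrelationNetwork

__all__ = [
    "DistanceMatrix",
    "ShortestPathResult",
    "CentralityTable",
    "EdgeBetweennessTable",
    "to_distance",
    "shortest_paths",
    "node_centralities",
    "edge_betweenness",
]


@dataclass
class DistanceMatrix:
    d: np.ndarray
    node_names: list[str]

    @property
    def p(self) -> int:
        return self.d.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.node_names, columns=self.node_names)


@dataclass
class ShortestPathResult:
    """All-pairs geodesic lengths plus the selected path per unordered pair."""

    lengths: np.ndarray
    paths: dict[tuple[int, int], tuple[int, ...]]  # key (i, j) with i < j
    node_names: list[str]

    def path_between(self, a: int, b: int) -> tuple[int, ...] | None:
        if a == b:
            return (a,)
        key = (min(a, b), max(a, b))
        p = self.paths.get(key)
        if p is None:
            return None
        return p if p[0] == a else tuple(reversed(p))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.lengths, index=self.node_names, columns=self.node_names)


@dataclass
class CentralityTable:
    table: pd.DataFrame  # strength, closeness, betweenness, expected_influence + z_*

    INDICES = ("strength", "closeness", "betweenness", "expected_influence")

    def __getitem__(self, key):
        return self.table[key]

    def to_csv(self, path) -> None:
        df = self.table.copy()
        df.index.name = "node"
        df.to_csv(path)


@dataclass
class EdgeBetweennessTable:
    table: pd.DataFrame  # node_i, node_j, weight, betweenness

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _weights(network) -> np.ndarray:
    if isinstance(network, PartialCorrelationNetwork):
        return network.weights
    return np.asarray(network, dtype=float)


def _names(network, p: int) -> list[str]:
    if isinstance(network, PartialCorrelationNetwork):
        return list(network.node_names)
    return [f"V{i + 1}" for i in range(p)]


def to_distance(network) -> DistanceMatrix:
    """d_ij = 1/|w_ij| for present edges, infinity for absent ones."""
    w = _weights(network)
    with np.errstate(divide="ignore"):
        d = np.where(w != 0.0, 1.0 / np.abs(w), np.inf)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d, _names(network, w.shape[0]))


def _dijkstra_lex(d: np.ndarray, source: int) -> tuple[np.ndarray, list[tuple[int, ...] | None]]:
    """Dijkstra from one source; among equal-length geodesics the heap order
    (distance, node sequence) selects the lexicographically smallest path."""
    p = d.shape[0]
    dist = np.full(p, np.inf)
    best: list[tuple[int, ...] | None] = [None] * p
    settled = np.zeros(p, dtype=bool)
    heap: list[tuple[float, tuple[int, ...]]] = [(0.0, (source,))]
    while heap:
        dd, path = heapq.heappop(heap)
        u = path[-1]
        if settled[u]:
            continue
        settled[u] = True
        dist[u] = dd
        best[u] = path
        row = d[u]
        for v in range(p):
            if not settled[v] and np.isfinite(row[v]):
                heapq.heappush(heap, (dd + row[v], path + (v,)))
    return dist, best


def shortest_paths(dmat: DistanceMatrix | np.ndarray) -> ShortestPathResult:
    """All-pairs Dijkstra with deterministic lexicographic tie-breaking.

    The selected geodesic for an unordered pair is computed from the
    smaller-indexed endpoint.  Unreachable pairs get infinite length and no
    path.
    """
    if isinstance(dmat, DistanceMatrix):
        d, names = dmat.d, dmat.node_names
    else:
        d = np.asarray(dmat, dtype=float)
        names = [f"V{i + 1}" for i in range(d.shape[0])]
    if np.any(d < 0):
        raise ValueError("distances must be nonnegative")
    p = d.shape[0]
    lengths = np.full((p, p), np.inf)
    np.fill_diagonal(lengths, 0.0)
    paths: dict[tuple[int, int], tuple[int, ...]] = {}
    for i in range(p):
        dist, best = _dijkstra_lex(d, i)
        lengths[i, :] = dist
        for j in range(i + 1, p):
            if best[j] is not None and np.isfinite(dist[j]):
                paths[(i, j)] = best[j]
    lengths = np.minimum(lengths, lengths.T)  # symmetric by construction
    return ShortestPathResult(lengths, paths, names)


def _zscore(col: np.ndarray) -> np.ndarray:
    sd = col.std()
    if sd == 0:
        return np.zeros_like(col)
    return (col - col.mean()) / sd


def node_centralities(
    network,
    counting: str = "selected-path",
) -> CentralityTable:
    """Strength, closeness, betweenness and expected influence per node.

    ``counting="selected-path"`` counts, for each node, the unordered pairs
    whose single selected geodesic has the node in its interior (integer
    counts).  ``counting="brandes"`` uses fractional counting over all
    geodesics (networkx).
    """
    w = _weights(network)
    p = w.shape[0]
    if p < 2:
        raise ValueError("need at least two nodes")
    names = _names(network, p)
    strength = np.abs(w).sum(axis=1)
    expected_influence = w.sum(axis=1)

    sp = shortest_paths(to_distance(w))
    closeness = np.zeros(p)
    for i in range(p):
        reach = np.isfinite(sp.lengths[i]) & (np.arange(p) != i)
        total = sp.lengths[i, reach].sum()
        closeness[i] = 1.0 / total if reach.any() and total > 0 else 0.0

    if counting == "selected-path":
        betw = np.zeros(p)
        for (_, _), path in sp.paths.items():
            for node in path[1:-1]:
                betw[node] += 1
    elif counting == "brandes":
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(range(p))
        for i in range(p):
            for j in range(i + 1, p):
                if w[i, j] != 0:
                    g.add_edge(i, j, distance=1.0 / abs(w[i, j]))
        bc = nx.betweenness_centrality(g, weight="distance", normalized=False)
        betw = np.array([bc[i] for i in range(p)])
    else:
        raise ValueError(f"unknown counting {counting!r}")

    df = pd.DataFrame(
        {
            "strength": strength,
            "closeness": closeness,
            "betweenness": betw,
            "expected_influence": expected_influence,
        },
        index=names,
    )
    for c in CentralityTable.INDICES:
        df[f"z_{c}"] = _zscore(df[c].to_numpy())
    return CentralityTable(df)


def edge_betweenness(network) -> EdgeBetweennessTable:
    """Per present edge: number of unordered node pairs whose selected
    geodesic traverses it.  A pair whose geodesic is its own direct edge
    contributes 1 to that edge."""
    w = _weights(network)
    p = w.shape[0]
    if p < 2:
        raise ValueError("need at least two nodes")
    names = _names(network, p)
    counts: dict[tuple[int, int], int] = {
        (i, j): 0 for i in range(p) for j in range(i + 1, p) if w[i, j] != 0
    }
    sp = shortest_paths(to_distance(w))
    for (_, _), path in sp.paths.items():
        for a, b in zip(path[:-1], path[1:]):
            key = (min(a, b), max(a, b))
            counts[key] += 1
    rows = [
        (names[i], names[j], w[i, j], c) for (i, j), c in sorted(counts.items())
    ]
    return EdgeBetweennessTable(
        pd.DataFrame(rows, columns=["node_i", "node_j", "weight", "betweenness"])
    )
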