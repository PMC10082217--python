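"""Undirected simple graphs: construction, generators, distances, rewiring, I/O.

All networks in this package are undirected, unweighted simple graphs.  Node
identifiers are opaque strings internally; wherever iteration order matters a
deterministic lexicographic order over the string identifiers is used, so
every operation is reproducible given a seed.
"""

from __future__ import annotations

import logging
from collections.abc import Hashable, Iterable, Sequence
from pathlib import Path

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

#: Marker used in DistanceMatrix entries for unreachable node pairs.
UNREACHABLE = -1


class ConnectivityError(RuntimeError):
    """Raised when a connected graph cannot be produced."""


class EdgeListParseError(ValueError):
    """Raised on a malformed edge-list line; carries the line number."""

    def __init__(self, message: str, line_number: int):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


def _as_rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


class Network:
    """An undirected simple graph with string node identifiers.

    Self-loops and duplicate edges are rejected at construction.  Nodes are
    exposed in sorted (lexicographic) order; ``index`` maps each identifier to
    its position in that order.

    Parameters
    ----------
    edges
        Iterable of node-identifier pairs.  Identifiers are converted to
        strings.
    nodes
        Optional extra node identifiers (e.g. isolated nodes); endpoints of
        ``edges`` are always included.
    """

    def __init__(
        self,
        edges: Iterable[tuple[Hashable, Hashable]],
        nodes: Iterable[Hashable] = (),
    ):
        g = nx.Graph()
        g.add_nodes_from(str(v) for v in nodes)
        seen: set[frozenset[str]] = set()
        for a, b in edges:
            u, v = str(a), str(b)
            if u == v:
                raise ValueError(f"self-loop on node {u!r} not allowed")
            key = frozenset((u, v))
            if key in seen:
                raise ValueError(f"duplicate edge {u!r}-{v!r} not allowed")
            seen.add(key)
            g.add_edge(u, v)
        self._g = g
        self._nodes: tuple[str, ...] = tuple(sorted(g.nodes))
        self._index = {v: i for i, v in enumerate(self._nodes)}

    # -- construction helpers -------------------------------------------------

    @classmethod
    def from_networkx(cls, g: nx.Graph) -> "Network":
        """Build a Network from a networkx graph (must be simple, undirected)."""
        if g.is_directed() or g.is_multigraph():
            raise ValueError("only simple undirected graphs are supported")
        return cls(g.edges, nodes=g.nodes)

    # -- basic accessors ------------------------------------------------------

    @property
    def nodes(self) -> tuple[str, ...]:
        """Node identifiers in deterministic sorted order."""
        return self._nodes

    @property
    def edges(self) -> list[tuple[str, str]]:
        """Edges as sorted (u, v) pairs with u < v, in deterministic order."""
        return sorted(tuple(sorted(e)) for e in self._g.edges)

    @property
    def n(self) -> int:
        return self._g.number_of_nodes()

    @property
    def m(self) -> int:
        return self._g.number_of_edges()

    @property
    def index(self) -> dict[str, int]:
        """Mapping from node identifier to position in ``nodes``."""
        return self._index

    def degree(self, node: Hashable) -> int:
        return self._g.degree[str(node)]

    def degree_sequence(self) -> tuple[int, ...]:
        """Sorted (ascending) degree multiset."""
        return tuple(sorted(d for _, d in self._g.degree))

    def neighbors(self, node: Hashable) -> list[str]:
        return sorted(self._g.neighbors(str(node)))

    def has_edge(self, u: Hashable, v: Hashable) -> bool:
        return self._g.has_edge(str(u), str(v))

    def is_connected(self) -> bool:
        return self.n > 0 and nx.is_connected(self._g)

    def to_networkx(self) -> nx.Graph:
        """A copy of the underlying networkx graph."""
        return self._g.copy()

    @property
    def graph(self) -> nx.Graph:
        """The underlying networkx graph (treat as read-only)."""
        return self._g

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Network):
            return NotImplemented
        return self._nodes == other._nodes and self.edges == other.edges

    def __repr__(self) -> str:  # pragma: no cover
        return f"Network(n={self.n}, m={self.m})"


class DistanceMatrix:
    """All-pairs hop (geodesic) distances for a Network.

    Entries are minimum edge counts; ``UNREACHABLE`` (−1) marks pairs in
    different components.  The matrix is symmetric with zero diagonal.
    """

    def __init__(self, nodes: Sequence[str], matrix: np.ndarray):
        self.nodes = tuple(nodes)
        self.index = {v: i for i, v in enumerate(self.nodes)}
        self.matrix = matrix

    def __getitem__(self, pair: tuple[Hashable, Hashable]) -> int:
        u, v = pair
        return int(self.matrix[self.index[str(u)], self.index[str(v)]])

    def row(self, node: Hashable) -> np.ndarray:
        """Distances from ``node`` to every node, in ``nodes`` order."""
        return self.matrix[self.index[str(node)]]

    def to_numpy(self) -> np.ndarray:
        return self.matrix.copy()


def all_pairs_hop_distance(net: Network) -> DistanceMatrix:
    """Breadth-first hop distances between every pair of nodes.

    Unreachable pairs (disconnected inputs) receive the ``UNREACHABLE``
    marker; connected inputs produce a fully finite matrix.
    """
    n = net.n
    mat = np.full((n, n), UNREACHABLE, dtype=np.int64)
    idx = net.index
    for src, lengths in nx.all_pairs_shortest_path_length(net.graph):
        i = idx[src]
        for tgt, d in lengths.items():
            mat[i, idx[tgt]] = d
    return DistanceMatrix(net.nodes, mat)


def average_degree(net: Network) -> float:
    """Mean degree 2m/n of the network."""
    if net.n == 0:
        raise ValueError("average degree undefined for an empty network")
    return 2.0 * net.m / net.n


def generate_er(
    n: int,
    avg_degree: float,
    seed: int | np.random.Generator,
    max_tries: int = 100,
) -> Network:
    """Connected Erdős–Rényi G(n, p) network with p = avg_degree/(n−1).

    Each node pair is linked independently with probability
    ``avg_degree/(n-1)``.  Because the propagation simulators assume every
    node is eventually informed, the draw is repeated (up to ``max_tries``
    times, advancing the random stream each attempt) until a connected graph
    appears.

    Raises
    ------
    ConnectivityError
        If no connected graph is produced within ``max_tries`` attempts,
        which is the expected outcome well below the connectivity threshold
        avg_degree ≈ ln n.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 < avg_degree <= n - 1:
        raise ValueError("avg_degree must be in (0, n-1]")
    p = min(avg_degree / (n - 1), 1.0)
    rng = _as_rng(seed)
    for _ in range(max_tries):
        g = nx.gnp_random_graph(n, p, seed=rng)
        if nx.is_connected(g):
            return Network.from_networkx(g)
    raise ConnectivityError(
        f"no connected G({n}, p={p:.4g}) draw in {max_tries} attempts; "
        "avg_degree is likely below the connectivity threshold"
    )


def generate_ba(
    n: int,
    links_per_node: int,
    seed: int | np.random.Generator,
) -> Network:
    """Barabási–Albert scale-free network grown by preferential attachment.

    Growth starts from a complete clique on ``links_per_node + 1`` nodes and
    adds the remaining nodes one at a time, each attaching
    ``links_per_node`` edges preferentially by degree.  The edge count is
    therefore deterministic:
    ``C(links_per_node+1, 2) + (n - links_per_node - 1) * links_per_node``,
    giving mean degree close to ``2 * links_per_node``.  The smallest case
    (n = links_per_node + 2) is well defined; n = 3, links_per_node = 1
    yields a 3-node tree (path).
    """
    if links_per_node < 1 or links_per_node >= n:
        raise ValueError("require 1 <= links_per_node < n")
    m0 = links_per_node + 1
    if n < m0:
        raise ValueError("n must be at least links_per_node + 1")
    rng = _as_rng(seed)
    g = nx.barabasi_albert_graph(
        n, links_per_node, seed=rng, initial_graph=nx.complete_graph(m0)
    )
    return Network.from_networkx(g)


def expected_ba_edges(n: int, links_per_node: int) -> int:
    """Deterministic edge count of :func:`generate_ba` for given parameters."""
    m0 = links_per_node + 1
    return m0 * (m0 - 1) // 2 + (n - m0) * links_per_node


def degree_preserving_rewire(
    net: Network,
    n_swaps: int,
    seed: int | np.random.Generator,
) -> Network:
    """Randomize a connected network by double-edge swaps, keeping degrees.

    Performs ``n_swaps`` swap *attempts*: each picks two distinct edges
    (a, b), (c, d) and proposes replacing them with (a, d), (c, b).  Proposals
    creating self-loops or duplicate edges are rejected; accepted swaps that
    disconnect the graph are rolled back.  The degree of every node — hence
    n, m and the degree multiset — is preserved exactly.  Graphs with no
    valid swap (e.g. a star) are returned unchanged.
    """
    if n_swaps < 0:
        raise ValueError("n_swaps must be non-negative")
    if not net.is_connected():
        raise ValueError("input network must be connected")
    rng = _as_rng(seed)
    g = net.to_networkx()
    edges = list(g.edges)
    for _ in range(n_swaps):
        i, j = rng.integers(0, len(edges), size=2)
        if i == j:
            continue
        a, b = edges[i]
        c, d = edges[j]
        if rng.random() < 0.5:
            c, d = d, c
        # proposed new edges: (a, d) and (c, b)
        if len({a, b, c, d}) < 4:
            continue
        if g.has_edge(a, d) or g.has_edge(c, b):
            continue
        g.remove_edge(a, b)
        g.remove_edge(c, d)
        g.add_edge(a, d)
        g.add_edge(c, b)
        if nx.is_connected(g):
            edges[i] = (a, d)
            edges[j] = (c, b)
        else:
            g.remove_edge(a, d)
            g.remove_edge(c, b)
            g.add_edge(a, b)
            g.add_edge(c, d)
    return Network.from_networkx(g)


def read_edge_list(path: str | Path) -> Network:
    """Read a plain-text edge list (one edge per line) into a Network.

    Columns may be separated by whitespace or a comma; lines starting with
    ``#`` and blank lines are ignored.  Duplicate and reversed duplicate
    edges are collapsed with a logged warning; self-loops and lines without
    exactly two columns raise :class:`EdgeListParseError` with the offending
    line number.
    """
    edges: list[tuple[str, str]] = []
    seen: set[frozenset[str]] = set()
    duplicates = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            tokens = [t for t in line.replace(",", " ").split() if t]
            if len(tokens) != 2:
                raise EdgeListParseError(
                    f"expected two columns, got {len(tokens)}: {line!r}", lineno
                )
            u, v = tokens
            if u == v:
                raise EdgeListParseError(f"self-loop {u!r}-{v!r}", lineno)
            key = frozenset((u, v))
            if key in seen:
                duplicates += 1
                continue
            seen.add(key)
            edges.append((u, v))
    if duplicates:
        logger.warning(
            "collapsed %d duplicate/reversed edge(s) while reading %s",
            duplicates,
            path,
        )
    return Network(edges)


def write_edge_list(net: Network, path: str | Path) -> None:
    """Write the network as a plain-text edge list (round-trips with reader)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# edge list: n={net.n} m={net.m}\n")
        for u, v in net.edges:
            fh.write(f"{u} {v}\n")
    isolated = [v for v in net.nodes if net.degree(v) == 0]
    if isolated:
        logger.warning(
            "%d isolated node(s) not representable in edge list", len(isolated)
        )


def write_adjacency_csv(net: Network, path: str | Path) -> None:
    """Write the 0/1 adjacency matrix as CSV (debugging aid)."""
    nodes = net.nodes
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("," + ",".join(nodes) + "\n")
        for u in nodes:
            row = ",".join("1" if net.has_edge(u, v) else "0" for v in nodes)
            fh.write(f"{u},{row}\n")
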