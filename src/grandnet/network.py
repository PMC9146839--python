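"""Simple undirected labelled graphs and induced subgraphs.

Nodes are the contiguous integers 0..N-1 internally; external string labels
are handled by the IO layer.  ``NetworkState`` is a lightweight mutable
adjacency structure tuned for the Metropolis moves: O(1) edge
insert/delete/membership, O(1) uniform random edge selection, and O(degree)
node insertion/removal.  All mutations can be recorded in a journal and
undone, which is how rejected resize proposals are rolled back without
copying the graph.  Conversion to :class:`networkx.Graph` is provided for
everything else.
"""

from __future__ import annotations

import numpy as np
import networkx as nx


class GraphValidationError(ValueError):
    """Raised when an edge set violates the simple-graph contract."""


def _canon(i: int, j: int) -> tuple[int, int]:
    return (i, j) if i < j else (j, i)


class NetworkState:
    """A simple undirected graph on nodes 0..N-1 with mutable edge set."""

    __slots__ = ("N", "edges", "adj", "_degrees", "_edge_list", "_edge_pos", "journal")

    def __init__(self, N: int, edges=()):
        if N < 0:
            raise GraphValidationError("N must be >= 0")
        self.N = int(N)
        self.edges: set[tuple[int, int]] = set()
        self.adj: list[set[int]] = [set() for _ in range(self.N)]
        self._degrees: list[int] = [0] * self.N
        self._edge_list: list[tuple[int, int]] = []
        self._edge_pos: dict[tuple[int, int], int] = {}
        self.journal: list | None = None
        for i, j in edges:
            self.add_edge(int(i), int(j))

    # -- mutation -----------------------------------------------------------

    def add_edge(self, i: int, j: int) -> None:
        if i == j:
            raise GraphValidationError(f"self-loop at node {i}")
        if not (0 <= i < self.N and 0 <= j < self.N):
            raise GraphValidationError(f"edge ({i},{j}) out of range for N={self.N}")
        e = _canon(i, j)
        if e in self.edges:
            raise GraphValidationError(f"duplicate edge {e}")
        self.edges.add(e)
        self._edge_pos[e] = len(self._edge_list)
        self._edge_list.append(e)
        self.adj[i].add(j)
        self.adj[j].add(i)
        self._degrees[i] += 1
        self._degrees[j] += 1
        if self.journal is not None:
            self.journal.append(("add", e))

    def remove_edge(self, i: int, j: int) -> None:
        e = _canon(i, j)
        if e not in self.edges:
            raise GraphValidationError(f"edge {e} not present")
        self.edges.remove(e)
        # swap-pop keeps random_edge O(1)
        pos = self._edge_pos.pop(e)
        last = self._edge_list.pop()
        if last != e:
            self._edge_list[pos] = last
            self._edge_pos[last] = pos
        i, j = e
        self.adj[i].discard(j)
        self.adj[j].discard(i)
        self._degrees[i] -= 1
        self._degrees[j] -= 1
        if self.journal is not None:
            self.journal.append(("remove", e))

    def add_node(self) -> int:
        """Append an isolated node; returns its index."""
        self.adj.append(set())
        self._degrees.append(0)
        self.N += 1
        if self.journal is not None:
            self.journal.append(("grow", None))
        return self.N - 1

    def pop_node(self) -> None:
        """Remove the last node, which must be isolated."""
        if self._degrees[-1] != 0:
            raise GraphValidationError("can only pop an isolated node")
        self.adj.pop()
        self._degrees.pop()
        self.N -= 1
        if self.journal is not None:
            self.journal.append(("shrink", None))

    def swap_nodes(self, a: int, b: int) -> None:
        """Exchange the labels of nodes a and b (journalled as edge moves)."""
        if a == b:
            return
        na = [u for u in self.adj[a] if u != b]
        nb = [u for u in self.adj[b] if u != a]
        linked = b in self.adj[a]
        if linked:
            self.remove_edge(a, b)
        for u in na:
            self.remove_edge(a, u)
        for u in nb:
            self.remove_edge(b, u)
        for u in na:
            self.add_edge(b, u)
        for u in nb:
            self.add_edge(a, u)
        if linked:
            self.add_edge(a, b)

    def start_journal(self) -> list:
        self.journal = []
        return self.journal

    def stop_journal(self) -> None:
        self.journal = None

    def undo(self, journal: list) -> None:
        """Revert all journalled mutations (most recent first)."""
        self.journal = None
        for op, e in reversed(journal):
            if op == "add":
                self.remove_edge(*e)
            elif op == "remove":
                self.add_edge(*e)
            elif op == "grow":
                self.pop_node()
            else:  # shrink
                self.add_node()

    def has_edge(self, i: int, j: int) -> bool:
        return _canon(i, j) in self.edges

    def random_edge(self, rng: np.random.Generator) -> tuple[int, int]:
        if not self._edge_list:
            raise GraphValidationError("graph has no edges")
        return self._edge_list[int(rng.integers(len(self._edge_list)))]

    # -- views --------------------------------------------------------------

    @property
    def degrees(self) -> np.ndarray:
        """Per-node degrees k_i = sum_j a_ij (a copy)."""
        return np.array(self._degrees, dtype=np.int64)

    def degree(self, i: int) -> int:
        return self._degrees[i]

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def copy(self) -> "NetworkState":
        out = NetworkState.__new__(NetworkState)
        out.N = self.N
        out.edges = set(self.edges)
        out.adj = [set(s) for s in self.adj]
        out._degrees = list(self._degrees)
        out._edge_list = list(self._edge_list)
        out._edge_pos = dict(self._edge_pos)
        out.journal = None
        return out

    def relabel(self, perm) -> "NetworkState":
        """Return the graph with node i renamed perm[i] (a permutation)."""
        perm = np.asarray(perm)
        if sorted(perm.tolist()) != list(range(self.N)):
            raise GraphValidationError("perm must be a permutation of 0..N-1")
        return NetworkState(self.N, ((int(perm[i]), int(perm[j])) for i, j in self.edges))

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.N))
        g.add_edges_from(self.edges)
        return g

    def edge_key(self) -> frozenset:
        """Hashable canonical identity of the edge set (for enumeration tests)."""
        return frozenset(self.edges)

    def __eq__(self, other):
        return (
            isinstance(other, NetworkState)
            and self.N == other.N
            and self.edges == other.edges
        )

    def __hash__(self):
        return hash((self.N, frozenset(self.edges)))

    def __repr__(self):
        return f"NetworkState(N={self.N}, L={self.n_edges})"


class ObservedSubgraph:
    """An induced subgraph G-hat on the sampled nodes 0..N_hat-1.

    Induced means: every link of the full network between two sampled nodes
    is present, so the observed degree kappa_i is a lower bound on the true
    degree k_i.
    """

    def __init__(self, state: NetworkState):
        self.graph = state
        self.N_hat = state.N
        self.kappa = state.degrees
        self.L_hat = state.n_edges

    @classmethod
    def from_edges(cls, N_hat: int, edges) -> "ObservedSubgraph":
        return cls(NetworkState(N_hat, edges))

    @classmethod
    def regular(cls, N_hat: int, kappa: int) -> "ObservedSubgraph":
        """A kappa-regular observed subgraph (circulant construction).

        Convenient for size-posterior studies that depend on the observed
        degrees only: the posterior over N under either ensemble is a
        function of (kappa, L_hat), not of which particular edges realise
        them.
        """
        if kappa >= N_hat:
            raise GraphValidationError("regular degree must be < N_hat")
        if (kappa * N_hat) % 2 != 0:
            raise GraphValidationError("kappa * N_hat must be even")
        edges = set()
        # connect each node to the next floor(kappa/2) neighbours around a ring,
        # plus the antipode when kappa is odd (requires even N_hat)
        for i in range(N_hat):
            for d in range(1, kappa // 2 + 1):
                edges.add(_canon(i, (i + d) % N_hat))
            if kappa % 2 == 1:
                edges.add(_canon(i, (i + N_hat // 2) % N_hat))
        return cls(NetworkState(N_hat, edges))

    def __repr__(self):
        return f"ObservedSubgraph(N_hat={self.N_hat}, L_hat={self.L_hat})"


def induced_subgraph(state: NetworkState, nodes) -> ObservedSubgraph:
    """Induced subgraph on ``nodes``; node i of the result is nodes[i]."""
    nodes = [int(v) for v in nodes]
    index = {v: i for i, v in enumerate(nodes)}
    if len(index) != len(nodes):
        raise GraphValidationError("node subset contains duplicates")
    edges = [
        (index[i], index[j])
        for i, j in state.edges
        if i in index and j in index
    ]
    return ObservedSubgraph(NetworkState(len(nodes), edges))
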