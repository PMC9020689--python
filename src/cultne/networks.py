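"""Prototype network topologies and network-constrained transmission.

Three classic undirected topologies restrict who can learn from whom:

* Erdos-Renyi random graphs — every pair connected independently with
  probability ``p`` (network density).
* Scale-free graphs grown by preferential attachment with tunable power
  ``pi_power``: each arriving node attaches two edges to existing nodes
  chosen with probability proportional to ``degree ** pi_power``.
* Watts-Strogatz small worlds — a ring lattice with ``K`` neighbours on
  either side, each edge rewired with probability ``p_r``.

During network-constrained transmission the learner occupying node ``v``
copies a uniformly random *neighbour* of ``v`` in the parental generation
(never itself), or innovates with probability ``mu``. Node positions are
heritable slots: generation t's learner at node v becomes generation
t+1's parent at node v.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import networkx as nx
import numpy as np

from .population import OffspringCounts, Population, _check_mu, _innovate

__all__ = [
    "Graph",
    "erdos_renyi",
    "barabasi_albert",
    "watts_strogatz",
    "network_step",
    "read_edgelist",
]


@dataclass
class Graph:
    """Undirected simple graph on nodes ``0..n-1`` in CSR adjacency form.

    ``neighbors[offsets[v]:offsets[v+1]]`` lists the neighbours of ``v``.
    Node indices map one-to-one onto positions in a :class:`Population`.
    """

    n: int
    offsets: np.ndarray
    neighbors: np.ndarray
    params: dict[str, Any] = field(default_factory=dict)

    @property
    def degrees(self) -> np.ndarray:
        return np.diff(self.offsets)

    @property
    def n_edges(self) -> int:
        return self.neighbors.size // 2

    @classmethod
    def from_edges(cls, n: int, edges: np.ndarray,
                   params: dict[str, Any] | None = None) -> "Graph":
        """Build from an ``(m, 2)`` array of undirected edges."""
        edges = np.asarray(edges, dtype=np.int64).reshape(-1, 2)
        if edges.size:
            if edges.min() < 0 or edges.max() >= n:
                raise ValueError("edge endpoints must be node indices in 0..n-1")
            if np.any(edges[:, 0] == edges[:, 1]):
                raise ValueError("self-loops are not allowed")
            canon = np.sort(edges, axis=1)
            if np.unique(canon, axis=0).shape[0] != canon.shape[0]:
                raise ValueError("duplicate edges are not allowed")
            both = np.concatenate([canon, canon[:, ::-1]])
            order = np.lexsort((both[:, 1], both[:, 0]))
            both = both[order]
            nbr = both[:, 1]
            deg = np.bincount(both[:, 0], minlength=n)
        else:
            nbr = np.empty(0, dtype=np.int64)
            deg = np.zeros(n, dtype=np.int64)
        offsets = np.concatenate(([0], np.cumsum(deg)))
        return cls(n, offsets, nbr, params or {})

    @classmethod
    def from_networkx(cls, g: nx.Graph,
                      params: dict[str, Any] | None = None) -> "Graph":
        n = g.number_of_nodes()
        if set(g.nodes) != set(range(n)):
            g = nx.convert_node_labels_to_integers(g)
        edges = np.array(list(g.edges), dtype=np.int64).reshape(-1, 2)
        return cls.from_edges(n, edges, params)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n))
        g.add_edges_from(self.edge_list())
        return g

    def edge_list(self) -> np.ndarray:
        """Canonical ``(m, 2)`` edge array with u < v."""
        u = np.repeat(np.arange(self.n), self.degrees)
        mask = u < self.neighbors
        return np.column_stack([u[mask], self.neighbors[mask]])

    def write_edgelist(self, path) -> None:
        """Two-column whitespace-delimited edge list, 0-based indices."""
        np.savetxt(path, self.edge_list(), fmt="%d")

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.to_networkx(), path)


def read_edgelist(path, n: int | None = None) -> Graph:
    """Read a two-column edge list; ``n`` defaults to max index + 1."""
    edges = np.loadtxt(path, dtype=np.int64, ndmin=2)
    if n is None:
        n = int(edges.max()) + 1 if edges.size else 0
    return Graph.from_edges(n, edges)


def _int_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(2**31))


def erdos_renyi(n: int, p: float, rng: np.random.Generator) -> Graph:
    """Erdos-Renyi G(n, p): each of the n(n-1)/2 edges independent with prob p."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"edge probability p must lie in [0, 1], got {p!r}")
    g = nx.fast_gnp_random_graph(n, p, seed=_int_seed(rng))
    return Graph.from_networkx(g, {"model": "erdos_renyi", "p": p})


def barabasi_albert(n: int, pi_power: float, rng: np.random.Generator) -> Graph:
    """Preferential-attachment growth with attachment probability ~ k**pi_power.

    Growth starts from a two-node connected seed; every arriving node
    attaches two edges to distinct existing nodes sampled without
    replacement with probability proportional to ``degree ** pi_power``
    (``pi_power = 1`` is linear preferential attachment, > 1 super-linear,
    < 1 sub-linear). The resulting graph is connected with exactly
    ``2 (n - 2) + 1`` edges.
    """
    if n < 3:
        raise ValueError("preferential-attachment growth needs n >= 3")
    if pi_power < 0:
        raise ValueError("attachment power must be >= 0")
    deg = np.zeros(n, dtype=np.int64)
    edges = np.empty((2 * (n - 2) + 1, 2), dtype=np.int64)
    edges[0] = (0, 1)
    deg[0] = deg[1] = 1
    k = 1
    for new in range(2, n):
        if new == 2:
            targets = np.array([0, 1])
        else:
            w = deg[:new].astype(float) ** pi_power
            targets = rng.choice(new, size=2, replace=False, p=w / w.sum())
        for t in targets:
            edges[k] = (t, new)
            k += 1
        deg[targets] += 1
        deg[new] = 2
    return Graph.from_edges(n, edges, {"model": "barabasi_albert", "pi": pi_power})


def watts_strogatz(n: int, K: int, p_r: float, rng: np.random.Generator) -> Graph:
    """Watts-Strogatz ring lattice with K neighbours per side, rewired with p_r.

    The lattice has exactly ``n * K`` edges before and after rewiring;
    rewiring moves one endpoint of each selected edge to a uniform
    non-duplicate, non-self target.
    """
    if not 1 <= K < n / 2:
        raise ValueError(f"need 1 <= K < n/2, got K={K!r} for n={n!r}")
    if not 0.0 <= p_r <= 1.0:
        raise ValueError(f"rewiring probability p_r must lie in [0, 1], got {p_r!r}")
    g = nx.watts_strogatz_graph(n, 2 * K, p_r, seed=_int_seed(rng))
    return Graph.from_networkx(g, {"model": "watts_strogatz", "K": K, "p_r": p_r})


def network_step(pop: Population, graph: Graph, mu: float,
                 rng: np.random.Generator) -> tuple[Population, OffspringCounts]:
    """One generation of transmission restricted to graph neighbours.

    The learner at node ``v`` innovates with probability ``mu``, otherwise
    copies a uniformly random neighbour of ``v`` in the parental
    generation. An isolated node has no role models: unless it innovates it
    retains its variant and is credited as its own cultural parent, so the
    conservation of offspring counts over learners still holds.
    """
    _check_mu(mu)
    N = pop.N
    if graph.n != N:
        raise ValueError("graph node count must equal the population size")
    deg = graph.degrees
    connected = deg > 0
    pick = (rng.random(N) * deg).astype(np.int64)
    parents = np.arange(N)  # isolated nodes fall back to themselves
    idx = graph.offsets[:-1] + pick
    parents[connected] = graph.neighbors[idx[connected]]
    child = pop.variants[parents].copy()
    innovators, child, next_label = _innovate(child, pop.next_label, mu, rng)
    counts = np.bincount(parents[~innovators], minlength=N)
    return Population(child, next_label), OffspringCounts(counts, N, int(innovators.sum()))
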