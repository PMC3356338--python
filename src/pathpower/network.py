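"""Undirected gene networks.

A :class:`GeneNetwork` is a simple undirected graph over an *ordered* list of
gene identifiers.  The node order is fixed and defines the row/column order of
every covariance matrix built from the network and of the expression matrices
sampled from it.  networkx stands behind file formats and graph algorithms.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import networkx as nx


class GeneNetwork:
    """Simple undirected graph with a fixed node order.

    Self-loops are rejected; duplicate edges collapse silently (sets).
    """

    def __init__(self, nodes: Sequence[str], edges: Iterable[tuple[str, str]]):
        self.nodes: list[str] = list(nodes)
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError("duplicate node identifiers")
        self._index = {g: i for i, g in enumerate(self.nodes)}
        edge_set: set[tuple[int, int]] = set()
        for a, b in edges:
            if a == b:
                raise ValueError(f"self-loop on node {a!r}")
            try:
                i, j = self._index[a], self._index[b]
            except KeyError as exc:
                raise KeyError(f"edge endpoint {exc.args[0]!r} not a node") from exc
            edge_set.add((min(i, j), max(i, j)))
        self._edges = sorted(edge_set)

    # ------------------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self._edges)

    def edge_indices(self) -> list[tuple[int, int]]:
        """Edges as (i, j) index pairs with i < j, in sorted order."""
        return list(self._edges)

    def edges(self) -> list[tuple[str, str]]:
        return [(self.nodes[i], self.nodes[j]) for i, j in self._edges]

    def index_of(self, gene: str) -> int:
        return self._index[gene]

    def has_edge(self, a: str, b: str) -> bool:
        i, j = self._index[a], self._index[b]
        return (min(i, j), max(i, j)) in set(self._edges)

    def degrees(self) -> list[int]:
        deg = [0] * self.n_nodes
        for i, j in self._edges:
            deg[i] += 1
            deg[j] += 1
        return deg

    # ------------------------------------------------------------------
    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges())
        return g

    @classmethod
    def from_networkx(cls, graph: nx.Graph, nodes: Sequence[str] | None = None
                      ) -> "GeneNetwork":
        node_order = list(nodes) if nodes is not None else list(graph.nodes())
        return cls(node_order, ((str(a), str(b)) for a, b in graph.edges()))

    def relabeled(self, order: Sequence[str]) -> "GeneNetwork":
        """Same topology with nodes listed in a new order (a permutation)."""
        if sorted(order) != sorted(self.nodes):
            raise ValueError("order must be a permutation of the node set")
        return GeneNetwork(order, self.edges())


def giant_component(network: GeneNetwork) -> GeneNetwork:
    """Restrict to the largest connected component, preserving node order."""
    g = network.to_networkx()
    if g.number_of_nodes() == 0:
        return network
    largest = max(nx.connected_components(g), key=len)
    nodes = [n for n in network.nodes if n in largest]
    edges = [(a, b) for a, b in network.edges() if a in largest and b in largest]
    return GeneNetwork(nodes, edges)
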