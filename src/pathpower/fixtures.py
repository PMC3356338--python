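"""Synthetic fixtures: scale-free networks, pathway collections, datasets.

Real studies constrain ST III/IV with experimentally determined interaction
networks and GO-derived pathways.  This module generates structural stand-ins
so the whole framework is testable without downloads: preferential-attachment
(Barabasi--Albert) networks, overlapping pathways as breadth-first
neighborhoods of random roots, and labeled expression matrices with known
differentially expressed pathways.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .containers import CONTROL, TREATMENT, GroupedExpression, Pathway, PathwayCollection
from .network import GeneNetwork, giant_component
from .simulators import apply_factor_correlation

__all__ = [
    "FixtureSpec",
    "generate_fixture_network",
    "generate_fixture_pathways",
    "generate_fixture_dataset",
]


@dataclass
class FixtureSpec:
    n_genes: int = 150
    edges_per_node: int = 2
    n_pathways: int = 12
    pathway_size_range: tuple[int, int] = (8, 15)
    overlap_allowed: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.pathway_size_range
        if lo < 2 or hi < lo:
            raise ValueError("pathway sizes must satisfy 2 <= min <= max")
        if self.n_genes <= self.edges_per_node:
            raise ValueError("n_genes must exceed edges_per_node")


def generate_fixture_network(spec: FixtureSpec) -> GeneNetwork:
    """Seeded preferential-attachment network over synthetic gene ids."""
    g = nx.barabasi_albert_graph(spec.n_genes, spec.edges_per_node, seed=spec.seed)
    width = max(4, len(str(spec.n_genes)))
    mapping = {i: f"g{i + 1:0{width}d}" for i in g.nodes()}
    g = nx.relabel_nodes(g, mapping)
    nodes = [mapping[i] for i in range(spec.n_genes)]
    return giant_component(GeneNetwork.from_networkx(g, nodes=nodes))


def _bfs_order(adj: dict[str, list[str]], root: str,
               allowed: set[str]) -> list[str]:
    seen = {root}
    order = [root]
    queue = deque([root])
    while queue:
        node = queue.popleft()
        for nb in adj[node]:
            if nb in allowed and nb not in seen:
                seen.add(nb)
                order.append(nb)
                queue.append(nb)
    return order


def generate_fixture_pathways(
    network: GeneNetwork, spec: FixtureSpec
) -> PathwayCollection:
    """Pathways as truncated BFS neighborhoods of seeded random roots.

    With ``overlap_allowed=False`` the BFS is restricted to genes not yet
    claimed by an earlier pathway, so the sets come out pairwise disjoint.
    """
    if network.n_nodes == 0:
        raise ValueError("network is empty")
    lo, hi = spec.pathway_size_range
    if hi > network.n_nodes:
        raise ValueError("pathway size range exceeds the network size")
    rng = np.random.default_rng(spec.seed)
    adj: dict[str, list[str]] = {g: [] for g in network.nodes}
    for a, b in network.edges():
        adj[a].append(b)
        adj[b].append(a)
    available = set(network.nodes)
    pathways: list[Pathway] = []
    attempts = 0
    while len(pathways) < spec.n_pathways:
        attempts += 1
        if attempts > 50 * spec.n_pathways:
            raise ValueError(
                f"could not place {spec.n_pathways} pathways of sizes {lo}-{hi} "
                f"(placed {len(pathways)}); relax the spec or allow overlap"
            )
        size = int(rng.integers(lo, hi + 1))
        pool = sorted(available) if not spec.overlap_allowed else network.nodes
        if not pool:
            raise ValueError("no genes left for disjoint pathways")
        root = pool[int(rng.integers(len(pool)))]
        allowed = available if not spec.overlap_allowed else set(network.nodes)
        order = _bfs_order(adj, root, allowed)
        if len(order) < size:
            continue
        genes = order[:size]
        pathways.append(Pathway(f"pw_{len(pathways) + 1:03d}", genes))
        if not spec.overlap_allowed:
            available -= set(genes)
    return PathwayCollection(pathways)


def generate_fixture_dataset(
    n_genes: int = 200,
    n_pathways: int = 20,
    pathway_size: int = 10,
    n_per_group: int = 40,
    rho: float = 0.3,
    effect_size: float = 1.0,
    de_fraction: float = 0.5,
    seed: int = 0,
) -> tuple[GroupedExpression, PathwayCollection]:
    """Labeled expression matrix with a known subset of DE pathways.

    Non-overlapping pathways of equal size over the first genes of the
    universe; each pathway gets its own latent factor at correlation ``rho``;
    the first ``ceil(de_fraction * n_pathways)`` pathways are shifted by
    ``effect_size`` in the treatment group (detection call 1).
    """
    if n_pathways * pathway_size > n_genes:
        raise ValueError("pathways do not fit into the gene universe")
    rng = np.random.default_rng(seed)
    width = max(4, len(str(n_genes)))
    genes = [f"g{i + 1:0{width}d}" for i in range(n_genes)]
    values = rng.standard_normal((n_genes, 2 * n_per_group))
    labels = np.asarray([CONTROL] * n_per_group + [TREATMENT] * n_per_group)
    pathways = []
    n_de = math.ceil(de_fraction * n_pathways)
    for k in range(n_pathways):
        members = genes[k * pathway_size:(k + 1) * pathway_size]
        idx = slice(k * pathway_size, (k + 1) * pathway_size)
        values[idx] = apply_factor_correlation(values[idx], rho, rng=rng)
        truly_de = k < n_de
        if truly_de:
            values[idx, n_per_group:] += effect_size
        pathways.append(
            Pathway(
                f"pw_{k + 1:03d}", members, truly_de=truly_de,
                realized_detection_call=1.0 if truly_de else 0.0,
            )
        )
    expr = GroupedExpression(values, genes, labels)
    return expr, PathwayCollection(pathways)
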