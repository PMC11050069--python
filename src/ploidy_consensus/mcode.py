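"""MCODE molecular-complex detection on a gene-interaction graph.

The classic three-stage algorithm: (1) weight every vertex by the density
of the highest k-core of its closed neighborhood times that core's k;
(2) seed greedy complexes at the highest-weight unused vertex, absorbing
neighbors whose weight is within a vertex-weight-percentage (VWP) of the
seed's, without node reuse across complexes; (3) post-process with an
optional "haircut" (trim singly connected vertices, i.e. keep the 2-core).
Complexes are scored by subgraph density times size and reported largest
score first. Ties among equal-weight seeds and equal-score complexes are
broken lexicographically by gene id so runs are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from .containers import validate_network


@dataclass
class McodeComplex:
    """One detected complex: member genes, seed, and density*size score."""

    members: frozenset[str]
    seed: str
    score: float
    density: float


def induced_subgraph(network: nx.Graph, genes) -> nx.Graph:
    """Subgraph on ``genes`` intersected with the network's nodes."""
    nodes = set(genes) & set(network.nodes)
    return nx.Graph(network.subgraph(nodes))


def _vertex_weight(network: nx.Graph, gene: str) -> float:
    """Highest-k-core weighting of the closed neighborhood of ``gene``."""
    closed = set(network.neighbors(gene)) | {gene}
    sub = network.subgraph(closed)
    if sub.number_of_edges() == 0:
        return 0.0
    cores = nx.core_number(sub)
    k_max = max(cores.values())
    core_nodes = [v for v, k in cores.items() if k >= k_max]
    core = sub.subgraph(core_nodes)
    return k_max * nx.density(core)


def mcode(
    network: nx.Graph,
    vwp: float = 0.2,
    haircut: bool = True,
    min_size: int = 3,
) -> list[McodeComplex]:
    """Extract node-disjoint dense complexes from ``network``.

    Parameters
    ----------
    vwp
        Vertex weight percentage in [0, 1): a neighbor joins the growing
        complex when its weight exceeds ``seed_weight * (1 - vwp)``.
    haircut
        Trim vertices with fewer than two connections inside the complex.
    min_size
        Complexes smaller than this (after the haircut) are discarded.
    """
    validate_network(network)
    weights = {v: _vertex_weight(network, v) for v in network.nodes}
    # highest weight first; gene id breaks ties deterministically
    order = sorted(network.nodes, key=lambda v: (-weights[v], v))
    used: set[str] = set()
    complexes: list[McodeComplex] = []
    for seed in order:
        if seed in used or weights[seed] <= 0:
            continue
        threshold = weights[seed] * (1.0 - vwp)
        members = {seed}
        frontier = [seed]
        while frontier:
            current = frontier.pop()
            for nbr in sorted(network.neighbors(current)):
                if nbr in used or nbr in members:
                    continue
                if weights[nbr] > threshold:
                    members.add(nbr)
                    frontier.append(nbr)
        used |= members
        sub = network.subgraph(members)
        if haircut:
            sub = nx.k_core(nx.Graph(sub), k=2)
            if sub.number_of_nodes() and not nx.is_connected(sub):
                anchor = seed if seed in sub else min(sub.nodes)
                component = nx.node_connected_component(sub, anchor)
                sub = sub.subgraph(component)
        size = sub.number_of_nodes()
        if size < min_size:
            continue
        density = nx.density(sub)
        complexes.append(
            McodeComplex(
                members=frozenset(sub.nodes),
                seed=seed,
                score=density * size,
                density=density,
            )
        )
    complexes.sort(key=lambda c: (-c.score, min(c.members)))
    return complexes
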