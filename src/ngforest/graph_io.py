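"""Protein-protein interaction network loading, validation and permutation.

The network is the substrate that constrains tree growth: every decision tree
is only allowed to test genes that form a connected subgraph of this network.
Gene identifiers are treated as case-sensitive opaque strings; no identifier
mapping is attempted.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable

import networkx as nx
import numpy as np

logger = logging.getLogger("ngforest")

__all__ = [
    "ProteinNetwork",
    "NetworkParseError",
    "load_network",
    "write_network",
    "restrict_to_measured",
    "permute_edges_degree_preserving",
]


class NetworkParseError(ValueError):
    """Raised when an edge-list / SIF file cannot be parsed."""


class ProteinNetwork:
    """Undirected, simple (no self-loops, no multi-edges) gene network.

    Thin wrapper over a :class:`networkx.Graph` providing the degree and
    neighborhood queries used during tree growth.
    """

    def __init__(self, edges: Iterable[tuple[str, str]] = (), nodes: Iterable[str] = ()):
        g = nx.Graph()
        g.add_nodes_from(nodes)
        for a, b in edges:
            if a != b:
                g.add_edge(a, b)
        self._g = g

    # -- construction ------------------------------------------------------
    @classmethod
    def from_graph(cls, g: nx.Graph) -> "ProteinNetwork":
        net = cls.__new__(cls)
        net._g = g
        return net

    # -- queries -----------------------------------------------------------
    @property
    def graph(self) -> nx.Graph:
        return self._g

    @property
    def nodes(self) -> set[str]:
        return set(self._g.nodes)

    @property
    def edges(self) -> set[frozenset[str]]:
        return {frozenset((a, b)) for a, b in self._g.edges}

    def n_nodes(self) -> int:
        return self._g.number_of_nodes()

    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def degree(self, gene: str) -> int:
        return self._g.degree[gene]

    def neighbors(self, gene: str) -> set[str]:
        return set(self._g.neighbors(gene))

    def has_node(self, gene: str) -> bool:
        return gene in self._g

    def degree_map(self) -> dict[str, int]:
        return dict(self._g.degree)

    def is_connected_subset(self, genes: set[str]) -> bool:
        """True iff ``genes`` induce a single connected subgraph (or are empty/singleton)."""
        genes = set(genes)
        if len(genes) <= 1:
            return True
        if not genes <= self.nodes:
            return False
        sub = self._g.subgraph(genes)
        return nx.is_connected(sub)

    def __eq__(self, other) -> bool:
        return isinstance(other, ProteinNetwork) and self.nodes == other.nodes and self.edges == other.edges

    def __repr__(self) -> str:
        return f"ProteinNetwork({self.n_nodes()} nodes, {self.n_edges()} edges)"


def load_network(path: str | Path, format: str = "edgelist") -> ProteinNetwork:
    """Load an undirected network from a two-column edge list or a SIF file.

    Duplicate edges (in either orientation) and self-loops are dropped with a
    logged count. Lines starting with ``#`` are comments. SIF lines are
    ``node <relation> node [node ...]``; each trailing node forms one edge with
    the first.
    """
    path = Path(path)
    if format not in ("edgelist", "sif"):
        raise ValueError(f"unknown network format {format!r}")
    g = nx.Graph()
    n_self, n_dup, n_lines = 0, 0, 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            n_lines += 1
            if format == "edgelist":
                if len(fields) < 2:
                    raise NetworkParseError(
                        f"{path}:{lineno}: expected at least 2 whitespace-separated fields, got {len(fields)}"
                    )
                pairs = [(fields[0], fields[1])]
            else:  # sif
                if len(fields) == 1:
                    pairs = []  # isolated node
                    g.add_node(fields[0])
                elif len(fields) < 3:
                    raise NetworkParseError(
                        f"{path}:{lineno}: SIF line needs node, relation, node(s); got {len(fields)} fields"
                    )
                else:
                    pairs = [(fields[0], t) for t in fields[2:]]
            for a, b in pairs:
                if a == b:
                    n_self += 1
                    g.add_node(a)  # the gene itself is kept
                elif g.has_edge(a, b):
                    n_dup += 1
                else:
                    g.add_edge(a, b)
    if n_lines == 0:
        raise NetworkParseError(f"{path}: no interactions found (empty file)")
    if n_self or n_dup:
        logger.info("load_network(%s): dropped %d self-loops, %d duplicate edges", path, n_self, n_dup)
    return ProteinNetwork.from_graph(g)


def write_network(net: ProteinNetwork, path: str | Path) -> None:
    """Write a tab-separated two-column edge list (round-trips with load_network)."""
    with open(path, "w") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in net.edges):
            fh.write(f"{a}\t{b}\n")
        for node in sorted(net.nodes):
            if net.degree(node) == 0:
                fh.write(f"# isolated\t{node}\n")


def restrict_to_measured(net: ProteinNetwork, genes: set[str]) -> ProteinNetwork:
    """Induced subgraph on the genes that are both in the network and measured.

    The result may be disconnected; each tree still grows inside one component
    by construction.
    """
    keep = net.nodes & set(genes)
    if not keep:
        raise ValueError(
            "no overlap between network nodes and measured genes; "
            "check that both files use the same gene identifier scheme"
        )
    return ProteinNetwork.from_graph(net.graph.subgraph(keep).copy())


def permute_edges_degree_preserving(
    net: ProteinNetwork, n_swaps: int | None = None, seed: int = 0
) -> ProteinNetwork:
    """Randomize edges while holding every node degree fixed.

    Uses repeated double-edge swaps, rejecting swaps that would create a
    self-loop or multi-edge, so the per-node degree map of the result is
    bit-identical to the input. ``n_swaps`` defaults to ``10 * |E|``, a
    standard mixing heuristic.
    """
    if n_swaps is None:
        n_swaps = 10 * net.n_edges()
    if n_swaps < 0:
        raise ValueError(f"n_swaps must be non-negative, got {n_swaps}")
    g = net.graph.copy()
    if n_swaps == 0:
        return ProteinNetwork.from_graph(g)
    if g.number_of_edges() < 2:
        raise ValueError("degree-preserving permutation needs at least 2 edges")
    rng = np.random.default_rng(seed)
    edges = [tuple(e) for e in g.edges]
    performed = 0
    attempts = 0
    max_attempts = max(100, 100 * n_swaps)
    while performed < n_swaps and attempts < max_attempts:
        attempts += 1
        i, j = rng.integers(0, len(edges), size=2)
        if i == j:
            continue
        (a, b), (c, d) = edges[i], edges[j]
        # swap to (a,d),(c,b); reject degenerate outcomes
        if len({a, b, c, d}) < 4:
            continue
        if g.has_edge(a, d) or g.has_edge(c, b):
            continue
        g.remove_edge(a, b)
        g.remove_edge(c, d)
        g.add_edge(a, d)
        g.add_edge(c, b)
        edges[i] = (a, d)
        edges[j] = (c, b)
        performed += 1
    if performed < n_swaps:
        logger.warning(
            "edge permutation performed %d/%d swaps before hitting the attempt cap", performed, n_swaps
        )
    return ProteinNetwork.from_graph(g)
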