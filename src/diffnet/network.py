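"""Undirected feature networks and their differential (topology-change) graph.

A :class:`Network` is a simple undirected graph over feature labels with edge
weights equal to the absolute partial correlation that produced the edge.
The :class:`DifferentialNetwork` of a high-grade and a low-grade network
contains exactly the edges whose presence differs between the two — the
symmetric difference of the edge sets.  An association present in both groups
carries no grade information and is dropped; what remains measures how much
each feature's dependency pattern rewires between grades.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

__all__ = ["Network", "DifferentialNetwork", "differential"]


def _key(i, j):
    """Canonical undirected edge key (sorted pair)."""
    return (i, j) if not j < i else (j, i)


@dataclass
class Network:
    """Undirected simple graph over feature labels.

    Parameters
    ----------
    nodes:
        Ordered node labels (feature indices or column names).
    edges:
        ``{(i, j): weight}`` with ``i``, ``j`` node labels; weights are
        absolute partial correlations.
    partial_corr:
        Optional full p x p partial-correlation matrix aligned with ``nodes``
        (kept so a differential network can weight edges by ``|R_hi - R_lo|``).
    group:
        Optional tag, e.g. ``"high"`` or ``"low"``.
    tau:
        Threshold used to build the edge set.
    """

    nodes: list
    edges: dict
    partial_corr: np.ndarray | None = None
    group: str | None = None
    tau: float | None = None

    def __post_init__(self) -> None:
        self.edges = {_key(*e): w for e, w in self.edges.items()}
        node_set = set(self.nodes)
        for i, j in self.edges:
            if i == j:
                raise ValueError(f"self-loop on node {i!r}")
            if i not in node_set or j not in node_set:
                raise ValueError(f"edge ({i!r}, {j!r}) references unknown node")
        self._pos = {v: k for k, v in enumerate(self.nodes)}

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edge_set(self) -> set:
        return set(self.edges)

    def has_edge(self, i, j) -> bool:
        return _key(i, j) in self.edges

    def degree(self, node) -> int:
        return sum(node in e for e in self.edges)

    def r_value(self, i, j) -> float:
        """Signed partial correlation for a pair (0.0 if no matrix stored)."""
        if self.partial_corr is None:
            return self.edges.get(_key(i, j), 0.0)
        return float(self.partial_corr[self._pos[i], self._pos[j]])

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from((i, j, {"weight": w}) for (i, j), w in self.edges.items())
        return g

    def to_edgelist(self) -> pd.DataFrame:
        rows = [(i, j, w) for (i, j), w in sorted(self.edges.items(), key=str)]
        return pd.DataFrame(rows, columns=["node_i", "node_j", "weight"])

    def to_adjacency(self) -> pd.DataFrame:
        A = np.zeros((self.n_nodes, self.n_nodes))
        for (i, j), w in self.edges.items():
            a, b = self._pos[i], self._pos[j]
            A[a, b] = A[b, a] = w
        return pd.DataFrame(A, index=self.nodes, columns=self.nodes)


@dataclass
class DifferentialNetwork:
    """Edges whose presence differs between the high- and low-grade networks.

    ``edges`` maps the pair to ``(weight, provenance)`` where provenance is
    ``"high-only"`` or ``"low-only"`` and the weight is ``|R_high - R_low|``
    on that pair.
    """

    nodes: list
    edges: dict  # (i, j) -> (weight, provenance)

    def __post_init__(self) -> None:
        self.edges = {_key(*e): v for e, v in self.edges.items()}

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edge_set(self) -> set:
        return set(self.edges)

    def degree(self, node) -> int:
        return sum(node in e for e in self.edges)

    def degrees(self) -> dict:
        d = {v: 0 for v in self.nodes}
        for i, j in self.edges:
            d[i] += 1
            d[j] += 1
        return d

    def strengths(self) -> dict:
        """Summed |delta R| of the incident differential edges per node."""
        s = {v: 0.0 for v in self.nodes}
        for (i, j), (w, _) in self.edges.items():
            s[i] += w
            s[j] += w
        return s

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(
            (i, j, {"weight": w, "provenance": prov})
            for (i, j), (w, prov) in self.edges.items()
        )
        return g

    def to_edgelist(self) -> pd.DataFrame:
        rows = [
            (i, j, w, prov)
            for (i, j), (w, prov) in sorted(self.edges.items(), key=str)
        ]
        return pd.DataFrame(rows, columns=["node_i", "node_j", "weight", "provenance"])


def differential(network_high: Network, network_low: Network) -> DifferentialNetwork:
    """Symmetric difference of the two grade networks' edge sets.

    An edge present in both inputs is removed (its dependency did not change
    between grades); an edge present in exactly one survives, tagged with its
    provenance and weighted by the absolute change in partial correlation.
    """
    if list(network_high.nodes) != list(network_low.nodes):
        raise ValueError("networks must share an identical (ordered) node set")
    eh, el = network_high.edge_set(), network_low.edge_set()
    out: dict = {}
    for e in eh ^ el:
        i, j = e
        w = abs(network_high.r_value(i, j) - network_low.r_value(i, j))
        out[e] = (w, "high-only" if e in eh else "low-only")
    return DifferentialNetwork(nodes=list(network_high.nodes), edges=out)
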