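"""Protein–protein interaction (PPI) network topology features.

The three topology features shared by all viability models live here:

* **LID** (local interaction density): the density of edges remaining
  between the direct neighbours of a protein after the protein itself is
  removed from the network.  A proxy for how internally connected the
  protein's molecular complex is.
* **SPL** (shortest path length): minimum number of edges separating two
  proteins.
* **SCL** (shortest circuit length): the closed-triangle circuit length
  connecting three proteins, taken as the sum of the three pairwise SPLs.

Disconnected queries return the :data:`UNREACHABLE` sentinel (``math.inf``)
rather than an arbitrary large distance; downstream encoders turn it into
an explicit indicator feature.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
from scipy.sparse.csgraph import shortest_path as _csgraph_shortest_path

logger = logging.getLogger(__name__)

#: Sentinel for a pair (or triple) of proteins with no connecting path.
UNREACHABLE = math.inf


class PPIParseError(ValueError):
    """Raised when a PPI edge-list file has a malformed line."""


class MissingGeneError(KeyError):
    """Raised when a queried gene is absent from the network."""


class PPINetwork:
    """Undirected, unweighted PPI graph over gene identifiers.

    Thin wrapper around :class:`networkx.Graph` that enforces the
    invariants the feature code relies on: no self-loops, deduplicated
    undirected edges.
    """

    def __init__(self, graph: nx.Graph | None = None):
        g = nx.Graph() if graph is None else nx.Graph(graph)
        loops = list(nx.selfloop_edges(g))
        if loops:
            logger.warning("dropping %d self-loop(s) from PPI network", len(loops))
            g.remove_edges_from(loops)
        self._g = g

    # -- construction ---------------------------------------------------
    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str]],
                   extra_nodes: Iterable[str] = ()) -> "PPINetwork":
        g = nx.Graph()
        g.add_nodes_from(extra_nodes)
        g.add_edges_from(edges)
        return cls(g)

    # -- container protocol ---------------------------------------------
    @property
    def graph(self) -> nx.Graph:
        return self._g

    @property
    def nodes(self) -> set[str]:
        return set(self._g.nodes)

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def __contains__(self, gene: str) -> bool:
        return gene in self._g

    def __len__(self) -> int:
        return self._g.number_of_nodes()

    def neighbors(self, gene: str) -> set[str]:
        return set(self._g.neighbors(gene))

    def degree(self, gene: str) -> int:
        return self._g.degree(gene)


def load_ppi(path) -> PPINetwork:
    """Load a PPI network from a two-column (tab/space) edge-list file.

    Lines starting with ``#`` are comments.  Duplicate edges (in either
    orientation) are collapsed; self-loops are dropped with a warning.

    Raises
    ------
    PPIParseError
        If a non-comment line does not have exactly two columns.
    """
    edges = []
    n_loops = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != 2:
                raise PPIParseError(
                    f"{path}: line {lineno}: expected 2 columns, got {len(fields)}"
                )
            a, b = fields
            if a == b:
                n_loops += 1
                continue
            edges.append((a, b))
    if n_loops:
        logger.warning("%s: dropped %d self-loop line(s)", path, n_loops)
    return PPINetwork.from_edges(edges)


def lid(net: PPINetwork, gene: str, *, normalized: bool = True,
        missing: str = "impute") -> float:
    """Local interaction density of ``gene``.

    With neighbour set ``N`` (of size ``k``) and ``E_N`` the number of
    network edges with both endpoints in ``N``, returns
    ``E_N / C(k, 2)``, which lies in [0, 1].  Genes with fewer than two
    neighbours have undefined density and return 0 by convention.

    Parameters
    ----------
    normalized:
        If ``False``, return the raw neighbour-edge count ``E_N``
        (the unnormalised variant used by some centrality composites).
    missing:
        ``"impute"`` (default) returns 0.0 for genes absent from the
        network (real screens contain genes missing from PPI data);
        ``"error"`` raises :class:`MissingGeneError`.
    """
    if gene not in net:
        if missing == "impute":
            logger.debug("gene %r absent from PPI network; LID imputed as 0", gene)
            return 0.0
        raise MissingGeneError(gene)
    nbrs = list(net.graph.neighbors(gene))
    k = len(nbrs)
    if k < 2:
        return 0.0
    e_n = net.graph.subgraph(nbrs).number_of_edges()
    if not normalized:
        return float(e_n)
    return e_n / (k * (k - 1) / 2)


def lid_table(net: PPINetwork, genes: Iterable[str] | None = None):
    """Per-gene LID table (columns: gene, degree, lid) as a DataFrame."""
    import pandas as pd

    genes = sorted(net.nodes) if genes is None else list(genes)
    rows = [
        (g, net.degree(g) if g in net else 0, lid(net, g))
        for g in genes
    ]
    return pd.DataFrame(rows, columns=["gene", "degree", "lid"])


def shortest_path_length(net: PPINetwork, a: str, b: str,
                         *, missing: str = "impute") -> float:
    """Shortest path length (edge count) between genes ``a`` and ``b``.

    Returns :data:`UNREACHABLE` when the genes are in different
    components (or absent from the network under ``missing="impute"``).
    """
    if a == b:
        raise ValueError("shortest_path_length requires two distinct genes")
    for g in (a, b):
        if g not in net:
            if missing == "impute":
                logger.debug("gene %r absent from network; SPL unreachable", g)
                return UNREACHABLE
            raise MissingGeneError(g)
    try:
        return float(nx.shortest_path_length(net.graph, a, b))
    except nx.NetworkXNoPath:
        return UNREACHABLE


def shortest_circuit_length(net: PPINetwork, a: str, b: str, c: str,
                            *, missing: str = "impute") -> float:
    """Shortest circuit length of a gene triple: SPL(a,b)+SPL(b,c)+SPL(a,c).

    The closed-triangle circuit visiting all three proteins.  Returns
    :data:`UNREACHABLE` if any pairwise term is unreachable.
    """
    if len({a, b, c}) != 3:
        raise ValueError("shortest_circuit_length requires three distinct genes")
    total = 0.0
    for x, y in ((a, b), (b, c), (a, c)):
        d = shortest_path_length(net, x, y, missing=missing)
        if d == UNREACHABLE:
            return UNREACHABLE
        total += d
    return total


class DistanceIndex:
    """All-pairs shortest-path cache for fast batch feature encoding.

    Computes the full SPL matrix once (BFS from every node via
    ``scipy.sparse.csgraph``) so that encoding hundreds of thousands of
    pairs or triplets is a vectorised table lookup.  Genes absent from
    the network map to UNREACHABLE distances and LID 0, matching the
    per-query functions.
    """

    def __init__(self, net: PPINetwork, genes: Iterable[str] | None = None):
        self.genes = sorted(net.nodes) if genes is None else list(genes)
        self.index: Mapping[str, int] = {g: i for i, g in enumerate(self.genes)}
        in_net = [g for g in self.genes if g in net]
        adj = nx.to_scipy_sparse_array(net.graph, nodelist=in_net, format="csr")
        d_net = _csgraph_shortest_path(adj, method="D", directed=False,
                                       unweighted=True)
        n = len(self.genes)
        self.spl = np.full((n, n), np.inf)
        np.fill_diagonal(self.spl, 0.0)
        pos = np.array([self.index[g] for g in in_net], dtype=int)
        self.spl[np.ix_(pos, pos)] = d_net
        self.lid = np.array([lid(net, g) for g in self.genes])

    def spl_of(self, a: str, b: str) -> float:
        return float(self.spl[self.index[a], self.index[b]])
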