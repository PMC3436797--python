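"""Undirected weighted interaction networks and edge-list I/O.

A :class:`Network` is the in-memory form of a protein–protein interaction
graph: an undirected, self-loop-free graph whose edge weights are interaction
confidences.  Nodes are opaque hashable identifiers (strings when read from
disk); a dense 0-based index over the nodes is maintained internally for
matrix work and never appears in outputs.

Edge lists use the de facto "ABC" format of MCL-family tools: one edge per
line, whitespace separated, ``nodeA nodeB`` or ``nodeA nodeB weight``.
Lines starting with ``#`` are comments.
"""

from __future__ import annotations

import logging
from typing import Hashable, Iterable, Iterator

import networkx as nx
import numpy as np
import scipy.sparse as sp

logger = logging.getLogger(__name__)

__all__ = ["Network", "read_edge_list", "min_max_normalize"]


class EdgeListParseError(ValueError):
    """Raised when an edge-list line cannot be parsed."""


class Network:
    """Undirected weighted graph without self-loops.

    Parameters
    ----------
    edges
        Iterable of ``(u, v)`` or ``(u, v, weight)`` tuples.  Self-loops are
        dropped; duplicate edges (in either orientation) are collapsed,
        keeping the maximum weight.  Missing weights default to 1.
    nodes
        Optional explicit node order.  Nodes not listed are appended in
        first-appearance order; listing a node absent from all edges is
        allowed but such a node is isolated and most pipeline entry points
        reject isolated nodes.

    Notes
    -----
    Weights must be strictly positive: a zero-confidence interaction is no
    interaction at all, and a zero weight would silently delete the edge
    from the stochastic flow matrix.
    """

    def __init__(
        self,
        edges: Iterable[tuple] = (),
        nodes: Iterable[Hashable] | None = None,
    ) -> None:
        self._index: dict[Hashable, int] = {}
        self._nodes: list[Hashable] = []
        self._weights: dict[tuple[int, int], float] = {}
        self.n_self_loops_dropped = 0
        self.n_duplicates_collapsed = 0
        if nodes is not None:
            for u in nodes:
                self._intern(u)
        for edge in edges:
            if len(edge) == 2:
                u, v = edge
                w = 1.0
            else:
                u, v, w = edge
            self.add_edge(u, v, w)

    def _intern(self, u: Hashable) -> int:
        i = self._index.get(u)
        if i is None:
            i = len(self._nodes)
            self._index[u] = i
            self._nodes.append(u)
        return i

    def add_edge(self, u: Hashable, v: Hashable, weight: float = 1.0) -> None:
        if weight <= 0 or not np.isfinite(weight):
            raise ValueError(f"edge ({u!r}, {v!r}) has non-positive weight {weight!r}")
        if u == v:
            self.n_self_loops_dropped += 1
            return
        i, j = self._intern(u), self._intern(v)
        key = (i, j) if i < j else (j, i)
        old = self._weights.get(key)
        if old is None:
            self._weights[key] = float(weight)
        else:
            self.n_duplicates_collapsed += 1
            self._weights[key] = max(old, float(weight))

    # -- basic accessors ---------------------------------------------------

    @property
    def nodes(self) -> list[Hashable]:
        return list(self._nodes)

    @property
    def n(self) -> int:
        return len(self._nodes)

    @property
    def n_edges(self) -> int:
        return len(self._weights)

    def index(self, u: Hashable) -> int:
        return self._index[u]

    def __contains__(self, u: Hashable) -> bool:
        return u in self._index

    def __len__(self) -> int:
        return len(self._nodes)

    def edges(self) -> Iterator[tuple[Hashable, Hashable, float]]:
        """Yield ``(u, v, weight)`` with u preceding v in node order."""
        for (i, j), w in self._weights.items():
            yield self._nodes[i], self._nodes[j], w

    def has_edge(self, u: Hashable, v: Hashable) -> bool:
        return self.weight(u, v) is not None

    def weight(self, u: Hashable, v: Hashable) -> float | None:
        i = self._index.get(u)
        j = self._index.get(v)
        if i is None or j is None or i == j:
            return None
        key = (i, j) if i < j else (j, i)
        return self._weights.get(key)

    def degrees(self) -> np.ndarray:
        """Number of neighbors of each node, in node order."""
        deg = np.zeros(self.n, dtype=np.intp)
        for i, j in self._weights:
            deg[i] += 1
            deg[j] += 1
        return deg

    def isolated_nodes(self) -> list[Hashable]:
        deg = self.degrees()
        return [self._nodes[i] for i in np.flatnonzero(deg == 0)]

    # -- conversions -------------------------------------------------------

    def adjacency_matrix(self) -> sp.csr_array:
        """Symmetric weighted adjacency matrix with zero diagonal (CSR)."""
        if not self._weights:
            return sp.csr_array((self.n, self.n))
        ij = np.array(list(self._weights.keys()), dtype=np.intp)
        w = np.fromiter(self._weights.values(), dtype=np.float64, count=len(self._weights))
        rows = np.concatenate([ij[:, 0], ij[:, 1]])
        cols = np.concatenate([ij[:, 1], ij[:, 0]])
        data = np.concatenate([w, w])
        return sp.csr_array((data, (rows, cols)), shape=(self.n, self.n))

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self._nodes)
        g.add_weighted_edges_from(self.edges())
        return g

    @classmethod
    def from_networkx(cls, g: nx.Graph) -> "Network":
        net = cls(nodes=g.nodes())
        for u, v, data in g.edges(data=True):
            net.add_edge(u, v, data.get("weight", 1.0))
        return net

    def induced_weight_sum(self, members: Iterable[Hashable]) -> float:
        """Total weight of edges with both endpoints in ``members``."""
        idx = {self._index[u] for u in members}
        total = 0.0
        if len(idx) * (len(idx) - 1) // 2 < len(self._weights):
            ordered = sorted(idx)
            for a, pi in enumerate(ordered):
                for pj in ordered[a + 1 :]:
                    w = self._weights.get((pi, pj))
                    if w is not None:
                        total += w
        else:
            for (i, j), w in self._weights.items():
                if i in idx and j in idx:
                    total += w
        return total

    def __repr__(self) -> str:  # pragma: no cover
        return f"Network(n={self.n}, n_edges={self.n_edges})"


def read_edge_list(path, weighted: bool = False) -> Network:
    """Read a whitespace-delimited edge list into a :class:`Network`.

    Parameters
    ----------
    path
        Path to the edge-list file.  Empty lines and lines starting with
        ``#`` are skipped.
    weighted
        If True, every edge line must carry a third token parsing as a
        positive real weight; if False, lines must have exactly two tokens
        and all weights are 1.

    Raises
    ------
    EdgeListParseError
        On a malformed line (with its line number) or a non-positive weight.
    ValueError
        If no edge survives self-loop removal.
    """
    net = Network()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split()
            expected = 3 if weighted else 2
            if len(tokens) != expected:
                raise EdgeListParseError(
                    f"{path}:{lineno}: expected {expected} fields, got {len(tokens)}: {line!r}"
                )
            u, v = tokens[0], tokens[1]
            if weighted:
                try:
                    w = float(tokens[2])
                except ValueError as exc:
                    raise EdgeListParseError(
                        f"{path}:{lineno}: weight {tokens[2]!r} is not a number"
                    ) from exc
                if w <= 0 or not np.isfinite(w):
                    raise EdgeListParseError(
                        f"{path}:{lineno}: weight must be a positive real, got {w}"
                    )
            else:
                w = 1.0
            net.add_edge(u, v, w)
    if net.n_edges == 0:
        raise ValueError(f"{path}: no edges remain after removing self-loops")
    if net.n_self_loops_dropped:
        logger.info("%s: dropped %d self-loop(s)", path, net.n_self_loops_dropped)
    if net.n_duplicates_collapsed:
        logger.info(
            "%s: collapsed %d duplicate edge(s), keeping the maximum weight",
            path,
            net.n_duplicates_collapsed,
        )
    return net


def min_max_scale(values: Iterable[float], eps: float = 0.01) -> list[float]:
    """Affine map sending min(values) to ``eps`` and max(values) to 1.

    Constant input maps to all ones.  This is the scalar kernel of
    :func:`min_max_normalize`, exposed for reuse on raw confidence scores
    (which, unlike stored edge weights, may legitimately include 0).
    """
    vals = list(values)
    if not vals:
        raise ValueError("no values to scale")
    lo, hi = min(vals), max(vals)
    if hi == lo:
        return [1.0] * len(vals)
    scale = (1.0 - eps) / (hi - lo)
    return [eps + (v - lo) * scale for v in vals]


def min_max_normalize(net: Network, eps: float = 0.01) -> Network:
    """Affinely rescale edge weights into ``[eps, 1]``.

    The maximum weight maps to 1 and the minimum to ``eps`` (> 0, so that no
    edge vanishes from the flow matrix); weight order is preserved.  If all
    weights are equal they all map to 1.
    """
    if net.n_edges == 0:
        raise ValueError("cannot normalize a network with no edges")
    if not 0 < eps < 1:
        raise ValueError(f"eps must lie in (0, 1), got {eps}")
    weights = [w for _, _, w in net.edges()]
    lo, hi = min(weights), max(weights)
    out = Network(nodes=net.nodes)
    if hi == lo:
        for u, v, _ in net.edges():
            out.add_edge(u, v, 1.0)
    else:
        scale = (1.0 - eps) / (hi - lo)
        for u, v, w in net.edges():
            out.add_edge(u, v, eps + (w - lo) * scale)
    return out
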