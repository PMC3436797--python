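"""Sparse column-stochastic flow machinery and a single R-MCL execution.

The engine simulates stochastic flow on a graph.  A column-stochastic matrix
``M`` holds transition probabilities: ``M[i, j]`` is the probability of
moving from node ``j`` to node ``i``.  Regularized Markov clustering (R-MCL)
alternates

* **Regularize** — ``M = M @ M_R``, where ``M_R`` is the (possibly
  balance-reweighted) canonical flow matrix of the graph, spreading flow
  along edges;
* **Inflate** — entrywise exponentiation followed by column renormalization,
  sharpening flow toward strong transitions;
* **Prune** — dropping negligible entries to keep the matrix sparse,

until the matrix stops changing.  At convergence the flow out of every node
concentrates on one *attractor* node; nodes sharing an attractor form a
cluster.

The soft variant reuses this engine with per-node *penalty counts*: the
inflation exponent for flow into node ``i`` is ``r * beta**counts[i]``, so
nodes that served as attractors in earlier executions attract flow less
strongly and later executions converge elsewhere.

All matrices are ``scipy.sparse`` CSC with sorted indices; every public
operation preserves column-stochasticity exactly (columns renormalized after
each step).  Everything here is deterministic — no randomness anywhere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .graph import Network

logger = logging.getLogger(__name__)

__all__ = [
    "RMCLParams",
    "canonical_flow_matrix",
    "regularize",
    "balanced_regularizer",
    "inflate_with_penalty",
    "prune",
    "extract_clusters",
    "run_rmcl",
    "flow_iterations",
]

#: column-sum tolerance for stochasticity checks
STOCHASTIC_TOL = 1e-10


@dataclass
class RMCLParams:
    """Parameters of one R-MCL execution.

    Attributes
    ----------
    r : float
        Inflation exponent, > 1.  Larger values give smaller, tighter
        clusters; 2.0 is the conventional choice.
    b : float
        Balance exponent, >= 0.  Penalizes flow toward nodes already
        attracting many nodes, discouraging giant clusters; 0 disables
        balancing.
    max_inner_iters : int
        Cap on Regularize/Inflate alternations.
    prune_threshold : float
        Entries below this are dropped after each inflation (the column
        maximum is always kept).
    convergence_tol : float
        Max-abs change between successive matrices defining convergence.
    """

    r: float = 2.0
    b: float = 0.5
    max_inner_iters: int = 100
    prune_threshold: float = 1e-5
    convergence_tol: float = 1e-6

    def __post_init__(self) -> None:
        if self.r <= 1:
            raise ValueError(f"inflation r must be > 1, got {self.r}")
        if self.b < 0:
            raise ValueError(f"balance b must be >= 0, got {self.b}")
        if self.prune_threshold <= 0 or self.convergence_tol <= 0:
            raise ValueError("prune_threshold and convergence_tol must be > 0")
        if self.max_inner_iters < 1:
            raise ValueError("max_inner_iters must be >= 1")


# ---------------------------------------------------------------------------
# column-wise primitives


def _as_csc(M) -> sp.csc_array:
    M = sp.csc_array(M)
    M.sort_indices()
    return M


def _col_ids(M: sp.csc_array) -> np.ndarray:
    """Column id of every stored entry."""
    return np.repeat(np.arange(M.shape[1]), np.diff(M.indptr))


def column_sums(M: sp.csc_array) -> np.ndarray:
    return np.asarray(M.sum(axis=0)).ravel()


def normalize_columns(M: sp.csc_array) -> sp.csc_array:
    """Divide each column by its sum.  Empty/zero columns are an error."""
    M = _as_csc(M.copy())
    M.eliminate_zeros()
    sums = column_sums(M)
    if np.any(sums <= 0):
        raise ValueError("cannot normalize a matrix with empty columns")
    M.data /= sums[_col_ids(M)]
    return M


def column_argmax(M: sp.csc_array) -> np.ndarray:
    """Row index of the largest entry in each column, lowest index on ties.

    Requires every column to hold at least one positive entry (true of any
    column-stochastic matrix).
    """
    M = _as_csc(M)
    n = M.shape[1]
    counts = np.diff(M.indptr)
    if np.any(counts == 0):
        raise ValueError("column_argmax: matrix has empty columns")
    starts = M.indptr[:-1]
    colmax = np.maximum.reduceat(M.data, starts)
    # first stored position attaining the column max; indices are sorted, so
    # the first position is the lowest row index
    pos = np.arange(M.nnz)
    is_max = M.data == colmax[_col_ids(M)]
    first = np.minimum.reduceat(np.where(is_max, pos, M.nnz), starts)
    return M.indices[first]


def is_column_stochastic(M, tol: float = STOCHASTIC_TOL) -> bool:
    M = _as_csc(M)
    if M.nnz and M.data.min() < 0:
        return False
    return bool(np.all(np.abs(column_sums(M) - 1.0) <= tol))


# ---------------------------------------------------------------------------
# flow operations


def canonical_flow_matrix(net: Network) -> sp.csc_array:
    """Column-normalize the weighted adjacency matrix of ``net``.

    Column ``j`` holds ``w(i, j) / sum_k w(k, j)`` over the neighbors ``i``
    of ``j``; the diagonal is zero (the graph has no self-loops).  Every
    node must have at least one neighbor.
    """
    isolated = net.isolated_nodes()
    if isolated:
        raise ValueError(
            f"canonical_flow_matrix: {len(isolated)} isolated node(s), e.g. "
            f"{isolated[0]!r}; remove them first"
        )
    return normalize_columns(_as_csc(net.adjacency_matrix()))


def regularize(M, M_R) -> sp.csc_array:
    """One Regularize step: the matrix product ``M @ M_R``.

    The product of two column-stochastic matrices is column-stochastic;
    columns are renormalized afterwards to shed accumulated float error.
    """
    M, M_R = _as_csc(M), _as_csc(M_R)
    if M.shape != M_R.shape:
        raise ValueError(f"dimension mismatch: {M.shape} vs {M_R.shape}")
    return normalize_columns(_as_csc(M @ M_R))


def balanced_regularizer(M_G, attractor_mass: np.ndarray, b: float) -> sp.csc_array:
    """Reweight the canonical flow matrix against crowded attractors.

    Each entry ``M_G[i, j]`` is scaled by ``attractor_mass[i] ** (-b)`` and
    columns are renormalized, reducing flow toward nodes that currently
    attract many others.  ``b = 0`` returns ``M_G`` unchanged.
    """
    M_G = _as_csc(M_G)
    if b == 0:
        return M_G
    mass = np.asarray(attractor_mass, dtype=np.float64)
    if mass.shape != (M_G.shape[0],):
        raise ValueError("attractor_mass must have one entry per node")
    if np.any(mass <= 0):
        raise ValueError("attractor_mass must be strictly positive")
    out = M_G.copy()
    out.data = out.data * mass[out.indices] ** (-b)
    return normalize_columns(out)


def inflate_with_penalty(
    M,
    r: float,
    beta: float = 1.0,
    counts: np.ndarray | None = None,
) -> sp.csc_array:
    """Entrywise exponentiation with per-row penalty exponents.

    Entry ``M[i, j]`` becomes ``M[i, j] ** (r * beta**counts[i])``, then each
    column is renormalized to sum 1.  With all counts zero (or ``beta = 1``)
    this is the classical Inflate with parameter ``r``.

    Penalized exponents grow geometrically with the count, so a column can
    underflow entirely; such a column is replaced by a point mass on its
    pre-inflation maximum entry (and the event is logged) rather than
    failing.
    """
    M = _as_csc(M)
    n = M.shape[0]
    if counts is None:
        counts = np.zeros(n)
    counts = np.asarray(counts, dtype=np.float64)
    if counts.shape != (n,):
        raise ValueError("counts must have one entry per node")
    if np.any(counts < 0):
        raise ValueError("counts must be nonnegative")
    if r <= 1:
        raise ValueError(f"inflation r must be > 1, got {r}")
    if beta < 1:
        raise ValueError(f"penalty ratio beta must be >= 1, got {beta}")

    argmax_before = column_argmax(M)
    out = M.copy()
    exponents = r * np.power(beta, counts[out.indices])
    with np.errstate(over="ignore", under="ignore"):
        out.data = np.power(out.data, exponents)
    out.data[~np.isfinite(out.data)] = 0.0
    out.eliminate_zeros()

    sums = np.zeros(n)
    np.add.at(sums, _col_ids(out), out.data)
    dead = np.flatnonzero(sums <= 0)
    if dead.size:
        logger.debug(
            "inflate: %d column(s) underflowed; falling back to point masses", dead.size
        )
        out = out.tolil()
        for j in dead:
            out[argmax_before[j], j] = 1.0
        out = _as_csc(out)
    return normalize_columns(out)


def prune(M, threshold: float) -> sp.csc_array:
    """Zero entries below ``threshold``, keep each column's maximum, renormalize."""
    if threshold < 0:
        raise ValueError("prune threshold must be >= 0")
    M = _as_csc(M)
    if threshold == 0:
        return M
    out = M.copy()
    starts = out.indptr[:-1]
    colmax = np.maximum.reduceat(out.data, starts) if out.nnz else np.array([])
    keep = (out.data >= threshold) | (out.data == colmax[_col_ids(out)])
    out.data = np.where(keep, out.data, 0.0)
    out.eliminate_zeros()
    return normalize_columns(out)


def extract_clusters(M) -> tuple[list[set[int]], set[int]]:
    """Read clusters off a converged flow matrix.

    Every node ``j`` is assigned to the attractor maximizing ``M[i, j]``
    (ties broken toward the lower node index), so the clusters partition the
    node set.  The attractor set — the nodes that receive some column's
    dominant flow — is also returned for the penalty bookkeeping of the
    soft outer loop.  (A node holding residual diagonal mass whose own flow
    departs elsewhere is not an attractor: nothing clusters around it.)
    """
    M = _as_csc(M)
    assign = column_argmax(M)
    attractors = set(np.unique(assign).tolist())
    clusters: dict[int, set[int]] = {}
    for j, a in enumerate(assign):
        clusters.setdefault(int(a), set()).add(j)
    ordered = [clusters[a] for a in sorted(clusters)]
    return ordered, attractors


def flow_iterations(
    M_G,
    params: RMCLParams,
    beta: float = 1.0,
    counts: np.ndarray | None = None,
):
    """Yield the flow matrix after each Regularize→Inflate→Prune iteration.

    The regularizer is rebuilt each iteration from the current attractor
    masses (column-argmax counts, minimum 1) so the balance term tracks the
    evolving clustering.  The generator stops after convergence (max-abs
    change below ``params.convergence_tol``), on a two-state oscillation, or
    at ``params.max_inner_iters``.
    """
    M_G = _as_csc(M_G)
    n = M_G.shape[0]
    M = M_G
    prev: sp.csc_array | None = None
    for it in range(params.max_inner_iters):
        masses = np.maximum(np.bincount(column_argmax(M), minlength=n), 1)
        M_R = balanced_regularizer(M_G, masses, params.b)
        M_new = regularize(M, M_R)
        M_new = inflate_with_penalty(M_new, params.r, beta, counts)
        M_new = prune(M_new, params.prune_threshold)
        yield M_new
        residual = abs(M_new - M).max() if (M_new - M).nnz else 0.0
        logger.debug("flow iteration %d: residual %.3e", it + 1, residual)
        if residual <= params.convergence_tol:
            return
        if prev is not None:
            cycle = abs(M_new - prev).max() if (M_new - prev).nnz else 0.0
            if cycle <= params.convergence_tol:
                # period-2 oscillation (possible without self-loops): the
                # flip-flop equilibrium is the average of the two states
                logger.debug("flow oscillates between two states; averaging")
                yield normalize_columns(_as_csc((M_new + M) * 0.5))
                return
        prev, M = M, M_new
    logger.warning(
        "flow did not converge within %d iterations (residual %.3e); "
        "using the current matrix",
        params.max_inner_iters,
        residual,
    )


def run_rmcl(
    net: Network,
    params: RMCLParams | None = None,
    beta: float = 1.0,
    counts: np.ndarray | None = None,
) -> tuple[list[set[int]], set[int]]:
    """One full R-MCL execution on ``net``.

    Returns ``(clusters, attractors)`` in internal node-index space:
    clusters partition ``range(net.n)``.  With all ``counts`` zero this is
    plain R-MCL; nonzero counts penalize previous attractors as in the soft
    outer loop.
    """
    if params is None:
        params = RMCLParams()
    if net.n == 0:
        raise ValueError("cannot cluster an empty network")
    M_G = canonical_flow_matrix(net)
    M = M_G
    for M in flow_iterations(M_G, params, beta, counts):
        pass
    return extract_clusters(M)
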