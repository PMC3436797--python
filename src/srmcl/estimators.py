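"""Scikit-learn style estimators for hard and soft regularized Markov clustering.

:class:`RMCL` is the hard clusterer: one flow simulation, one label per
node.  :class:`SRMCL` is the soft variant: ``t`` penalized executions are
pooled and post-processed into an overlapping set of quality-filtered
clusters.  Both accept a :class:`~srmcl.graph.Network`, a
``networkx.Graph`` or a symmetric nonnegative (sparse or dense) adjacency
matrix, compose with ``sklearn.base.clone`` and ``get_params``/
``set_params``, and expose their results through trailing-underscore
attributes after :meth:`fit`.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
import scipy.sparse as sp
from sklearn.base import BaseEstimator, ClusterMixin

from .flow import RMCLParams, run_rmcl
from .graph import Network
from .postprocess import PostprocessParams, postprocess
from .soft import RawCluster, SRMCLParams, run_srmcl

__all__ = ["RMCL", "SRMCL", "as_network"]


def as_network(X) -> Network:
    """Coerce an input graph into a :class:`Network`.

    Accepts a Network (returned as-is), a networkx Graph, or a square
    symmetric nonnegative matrix (dense or sparse) whose entry ``(i, j)``
    is the weight of edge ``i–j``; the diagonal is ignored.
    """
    if isinstance(X, Network):
        return X
    if isinstance(X, nx.Graph):
        return Network.from_networkx(X)
    A = sp.coo_array(X) if sp.issparse(X) else sp.coo_array(np.asarray(X, dtype=float))
    if A.shape[0] != A.shape[1]:
        raise ValueError(f"adjacency matrix must be square, got {A.shape}")
    if (abs(A - A.T) > 1e-12).nnz:
        raise ValueError("adjacency matrix must be symmetric")
    if A.nnz and A.data.min() < 0:
        raise ValueError("adjacency matrix must be nonnegative")
    net = Network(nodes=range(A.shape[0]))
    for i, j, w in zip(A.row, A.col, A.data):
        if i < j and w > 0:
            net.add_edge(int(i), int(j), float(w))
    return net


class RMCL(ClusterMixin, BaseEstimator):
    """Regularized Markov clustering (hard, non-overlapping).

    Simulates stochastic flow on the graph by alternating Regularize
    (``M @ M_G`` against a balance-reweighted canonical flow matrix) and
    Inflate (entrywise power ``r``, column renormalization) until the flow
    concentrates on attractor nodes; nodes flowing to the same attractor
    form one cluster.

    Parameters
    ----------
    r : float, default=2.0
        Inflation exponent (> 1); larger values give finer clusters.
    b : float, default=0.5
        Balance exponent (>= 0) discouraging giant clusters; 0 disables.
    prune_threshold : float, default=1e-5
        Sparsity cutoff applied after each inflation.
    convergence_tol : float, default=1e-6
        Max-abs matrix change declaring convergence.
    max_iter : int, default=100
        Cap on flow iterations.

    Attributes
    ----------
    nodes_ : list
        Node identifiers in internal order.
    labels_ : ndarray of shape (n_nodes,)
        Cluster label of each node (a partition).
    clusters_ : list of frozenset
        The clusters as node-identifier sets, ordered by label.
    attractors_ : frozenset
        Node identifiers that attracted flow at convergence.
    """

    def __init__(
        self,
        r: float = 2.0,
        b: float = 0.5,
        prune_threshold: float = 1e-5,
        convergence_tol: float = 1e-6,
        max_iter: int = 100,
    ) -> None:
        self.r = r
        self.b = b
        self.prune_threshold = prune_threshold
        self.convergence_tol = convergence_tol
        self.max_iter = max_iter

    def _rmcl_params(self) -> RMCLParams:
        return RMCLParams(
            r=self.r,
            b=self.b,
            max_inner_iters=self.max_iter,
            prune_threshold=self.prune_threshold,
            convergence_tol=self.convergence_tol,
        )

    def fit(self, X, y=None) -> "RMCL":
        net = as_network(X)
        clusters, attractors = run_rmcl(net, self._rmcl_params())
        nodes = net.nodes
        labels = np.empty(net.n, dtype=np.intp)
        out = []
        for label, members in enumerate(clusters):
            out.append(frozenset(nodes[i] for i in members))
            for i in members:
                labels[i] = label
        self.nodes_ = nodes
        self.labels_ = labels
        self.clusters_ = out
        self.attractors_ = frozenset(nodes[i] for i in attractors)
        return self


class SRMCL(BaseEstimator):
    """Soft regularized Markov clustering (overlapping).

    Runs the hard clusterer ``t`` times.  After each execution the nodes
    that served as attractors are penalized: flow into a node that has been
    an attractor ``x`` times is inflated with exponent ``r * beta**x``, so
    later executions converge to different clusterings.  All executions'
    clusters are pooled and post-processed — size and quality filtering
    followed by redundancy removal at neighborhood-affinity threshold
    ``p`` — into an overlapping set of predicted modules.

    Parameters
    ----------
    r, b, prune_threshold, convergence_tol, max_iter
        As in :class:`RMCL`.
    t : int, default=30
        Number of penalized executions to pool (useful range 10–50).
    beta : float, default=1.25
        Penalty ratio (>= 1); 1 disables the penalty and every execution
        repeats the first.
    qf : {"density_sqrt_size", "density", "clustering_coefficient"}
        Cluster quality function used by post-processing.
    omega : float, default=1.0
        Quality threshold; clusters scoring below it are dropped.
    p : float, default=0.6
        Redundancy threshold; of two clusters with neighborhood affinity
        above ``p`` only the higher-quality one is kept.
    postprocess : bool, default=True
        If False, ``clusters_`` contains the pooled clusters unfiltered.

    Attributes
    ----------
    nodes_ : list
        Node identifiers in internal order.
    raw_clusters_ : list of (frozenset, int)
        Pooled deduplicated clusters with the 1-based execution that first
        produced each.
    clusters_ : list of frozenset
        Final predicted modules, in quality-descending order.
    scored_clusters_ : list of ScoredCluster
        The kept clusters with quality values (empty if postprocess=False).
    attractor_counts_ : dict
        Node identifier -> number of executions it attracted.
    """

    def __init__(
        self,
        r: float = 2.0,
        b: float = 0.5,
        t: int = 30,
        beta: float = 1.25,
        qf: str = "density_sqrt_size",
        omega: float = 1.0,
        p: float = 0.6,
        prune_threshold: float = 1e-5,
        convergence_tol: float = 1e-6,
        max_iter: int = 100,
        postprocess: bool = True,
    ) -> None:
        self.r = r
        self.b = b
        self.t = t
        self.beta = beta
        self.qf = qf
        self.omega = omega
        self.p = p
        self.prune_threshold = prune_threshold
        self.convergence_tol = convergence_tol
        self.max_iter = max_iter
        self.postprocess = postprocess

    def _srmcl_params(self) -> SRMCLParams:
        return SRMCLParams(
            rmcl=RMCLParams(
                r=self.r,
                b=self.b,
                max_inner_iters=self.max_iter,
                prune_threshold=self.prune_threshold,
                convergence_tol=self.convergence_tol,
            ),
            t=self.t,
            beta=self.beta,
        )

    def _postprocess_params(self) -> PostprocessParams:
        return PostprocessParams(qf_name=self.qf, omega=self.omega, p=self.p)

    def fit(self, X, y=None) -> "SRMCL":
        net = as_network(X)
        raw, state = run_srmcl(net, self._srmcl_params(), return_state=True)
        nodes = net.nodes
        raw_named = [
            RawCluster(frozenset(nodes[i] for i in rc.members), rc.source_iteration)
            for rc in raw
        ]
        self.nodes_ = nodes
        self.raw_clusters_ = [(rc.members, rc.source_iteration) for rc in raw_named]
        self.attractor_counts_ = {
            nodes[i]: int(c) for i, c in enumerate(state.counts) if c
        }
        if self.postprocess:
            kept = postprocess(raw_named, net, self._postprocess_params())
            self.scored_clusters_ = kept
            self.clusters_ = [sc.members for sc in kept]
        else:
            self.scored_clusters_ = []
            self.clusters_ = [rc.members for rc in raw_named]
        return self

    def fit_predict(self, X, y=None) -> np.ndarray:
        """Fit and return a binary membership matrix (clusters x nodes)."""
        self.fit(X)
        return self.membership_matrix()

    def membership_matrix(self) -> np.ndarray:
        """Binary (n_clusters, n_nodes) matrix of the fitted clusters."""
        index = {u: i for i, u in enumerate(self.nodes_)}
        out = np.zeros((len(self.clusters_), len(self.nodes_)), dtype=bool)
        for k, members in enumerate(self.clusters_):
            for u in members:
                out[k, index[u]] = True
        return out
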