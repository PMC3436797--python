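"""Cluster quality scoring and redundancy removal.

Pooling many clustering executions leaves low-quality and near-duplicate
clusters.  Post-processing (i) removes clusters of size <= 2, (ii) removes
clusters whose quality-function value falls below a threshold ``omega``, and
(iii) walks the survivors in descending quality order, discarding any
cluster whose neighborhood affinity with an already-kept (hence at least as
good) cluster exceeds the redundancy threshold ``p``.  Only what survives is
reported as a predicted functional module, so not every protein ends up in a
cluster.

Quality functions
-----------------
``density``
    Sum of induced edge weights over the number of possible pairs
    ``|c|(|c|-1)/2``; on unweighted graphs this is classic edge density.
``clustering_coefficient``
    Mean local clustering coefficient over members, computed on the induced
    unweighted subgraph (members of induced degree < 2 contribute 0).
``density_sqrt_size``
    ``density * sqrt(|c|)``.  Plain density favors tiny clusters on sparse
    interaction networks; the sqrt(size) factor counteracts that and is the
    recommended default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Hashable, Iterable, Sequence

import networkx as nx

from .graph import Network
from .soft import RawCluster

__all__ = [
    "ScoredCluster",
    "PostprocessParams",
    "density",
    "clustering_coefficient",
    "density_sqrt_size",
    "neighborhood_affinity",
    "postprocess",
    "QUALITY_FUNCTIONS",
]


def density(members: Iterable[Hashable], net: Network) -> float:
    """Induced edge-weight sum over the number of node pairs."""
    members = set(members)
    k = len(members)
    if k < 2:
        raise ValueError("density requires at least 2 members")
    return net.induced_weight_sum(members) / (k * (k - 1) / 2)


def clustering_coefficient(members: Iterable[Hashable], net: Network) -> float:
    """Mean local clustering coefficient in the induced unweighted subgraph."""
    members = set(members)
    if len(members) < 2:
        raise ValueError("clustering_coefficient requires at least 2 members")
    sub = nx.Graph()
    sub.add_nodes_from(members)
    ordered = sorted(members, key=str)
    for a, u in enumerate(ordered):
        for v in ordered[a + 1 :]:
            if net.has_edge(u, v):
                sub.add_edge(u, v)
    cc = nx.clustering(sub)  # 0 for degree < 2 nodes
    return sum(cc.values()) / len(members)


def density_sqrt_size(members: Iterable[Hashable], net: Network) -> float:
    """Density scaled by the square root of the cluster size."""
    members = set(members)
    return density(members, net) * math.sqrt(len(members))


QUALITY_FUNCTIONS: dict[str, Callable[[Iterable[Hashable], Network], float]] = {
    "density": density,
    "clustering_coefficient": clustering_coefficient,
    "density_sqrt_size": density_sqrt_size,
}


def neighborhood_affinity(c1: Iterable[Hashable], c2: Iterable[Hashable]) -> float:
    """Overlap score ``|c1 ∩ c2|**2 / (|c1| * |c2|)``.

    Symmetric, in [0, 1]; equals 1 iff the sets are identical and 0 iff
    disjoint.  Used both for redundancy removal among predicted clusters and
    for matching clusters against reference modules.
    """
    s1, s2 = set(c1), set(c2)
    if not s1 or not s2:
        raise ValueError("neighborhood affinity is undefined for empty sets")
    inter = len(s1 & s2)
    return inter * inter / (len(s1) * len(s2))


@dataclass(frozen=True)
class ScoredCluster:
    """A kept cluster with its quality value and originating execution."""

    members: frozenset
    qf_value: float
    source_iteration: int = 0


@dataclass
class PostprocessParams:
    """Quality threshold ``omega``, redundancy threshold ``p`` and the qf name.

    ``p`` controls the permitted overlap between kept clusters (higher p ->
    more, more-overlapping clusters; sensible range roughly 0.3–0.8).
    ``omega`` depends on the quality function and the network's density.
    """

    qf_name: str = "density_sqrt_size"
    omega: float = 1.0
    p: float = 0.6

    def __post_init__(self) -> None:
        if self.qf_name not in QUALITY_FUNCTIONS:
            raise ValueError(
                f"unknown quality function {self.qf_name!r}; "
                f"choose from {sorted(QUALITY_FUNCTIONS)}"
            )
        if not 0 <= self.p <= 1:
            raise ValueError(f"p must lie in [0, 1], got {self.p}")
        if self.omega < 0:
            raise ValueError(f"omega must be >= 0, got {self.omega}")

    @property
    def qf(self) -> Callable[[Iterable[Hashable], Network], float]:
        return QUALITY_FUNCTIONS[self.qf_name]


def _sort_key(sc: ScoredCluster):
    # qf descending, then size descending, then lexicographic members —
    # fully deterministic regardless of input order
    return (-sc.qf_value, -len(sc.members), tuple(sorted(sc.members, key=str)))


def postprocess(
    raw_clusters: Sequence[RawCluster | frozenset | set],
    net: Network,
    params: PostprocessParams | None = None,
) -> list[ScoredCluster]:
    """Filter and deduplicate pooled clusters.

    Steps: drop size <= 2; drop quality < omega; sort remaining by quality
    descending; keep a cluster only if its neighborhood affinity with every
    already-kept cluster is <= p (strictly greater removes, so NA == p
    survives).  The result is returned in kept (quality-descending) order;
    every kept pair has NA <= p, size >= 3 and qf >= omega.
    """
    if params is None:
        params = PostprocessParams()
    scored = []
    for rc in raw_clusters:
        if isinstance(rc, RawCluster):
            members, src = rc.members, rc.source_iteration
        else:
            members, src = frozenset(rc), 0
        if len(members) <= 2:
            continue
        q = params.qf(members, net)
        if q < params.omega:
            continue
        scored.append(ScoredCluster(members, q, src))
    scored.sort(key=_sort_key)
    kept: list[ScoredCluster] = []
    for cand in scored:
        if all(
            neighborhood_affinity(cand.members, k.members) <= params.p for k in kept
        ):
            kept.append(cand)
    return kept
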