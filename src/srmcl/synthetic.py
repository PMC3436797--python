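"""Planted-module benchmark networks with overlaps, bridges and noise.

Real interactome benchmarks depend on database releases; these generators
instead plant known modules in a synthetic graph so every structural claim
about the clustering pipeline can be checked against ground truth.  Three
canonical structures mirror the failure modes of hard clustering:

* two dense modules sharing a single *bridge* node (hard clustering merges
  them, the bridge becoming the attractor of the merged cluster);
* two modules whose memberships overlap heavily (a partition cannot
  represent both);
* a parent module containing two tightly-knit child modules (a partition
  recovers one level of the hierarchy only).

A randomized benchmark plants many partially-overlapping modules plus
random inter-module noise edges, emulating the overlap statistics of
protein functional annotation at desk scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .graph import Network

__all__ = [
    "ModuleSpec",
    "PlantedSpec",
    "generate",
    "bridged_modules_fixture",
    "overlapping_modules_fixture",
    "nested_modules_fixture",
    "planted_benchmark",
]


@dataclass(frozen=True)
class ModuleSpec:
    """One planted module: members, internal edge probability, edge weight."""

    members: tuple
    p_in: float = 1.0
    weight: float = 1.0

    def __post_init__(self) -> None:
        if len(self.members) < 3:
            raise ValueError("planted modules must have >= 3 members")
        if len(set(self.members)) != len(self.members):
            raise ValueError("module members must be distinct")
        if not 0 < self.p_in <= 1:
            raise ValueError("internal edge probability must lie in (0, 1]")
        if self.weight <= 0:
            raise ValueError("module edge weight must be positive")


@dataclass
class PlantedSpec:
    """Specification of a planted-module network.

    Modules may share members (overlaps/bridges are expressed simply by
    listing a node in several modules).  ``noise_edges`` random edges are
    added between node pairs that share no module; alternatively
    ``noise_fraction`` requests a number of noise edges proportional to the
    realized count of module-internal edges.  All randomness derives from
    ``seed``.
    """

    modules: Sequence[ModuleSpec]
    noise_edges: int = 0
    noise_fraction: float | None = None
    noise_weight: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.modules:
            raise ValueError("at least one module is required")
        if self.noise_edges < 0:
            raise ValueError("noise_edges must be >= 0")
        if self.noise_fraction is not None and self.noise_fraction < 0:
            raise ValueError("noise_fraction must be >= 0")


def _module_edges(mod: ModuleSpec, rng: np.random.Generator) -> list[tuple]:
    members = list(mod.members)
    k = len(members)
    if mod.p_in == 1.0:
        return [
            (members[a], members[b], mod.weight)
            for a in range(k)
            for b in range(a + 1, k)
        ]
    # a random Hamiltonian path keeps the module connected whatever p_in is
    order = list(rng.permutation(k))
    edges = {frozenset((members[order[i]], members[order[i + 1]])) for i in range(k - 1)}
    for a in range(k):
        for b in range(a + 1, k):
            pair = frozenset((members[a], members[b]))
            if pair not in edges and rng.random() < mod.p_in:
                edges.add(pair)
    return [(u, v, mod.weight) for u, v in (sorted(e, key=str) for e in edges)]


def generate(spec: PlantedSpec) -> tuple[Network, dict[str, frozenset]]:
    """Realize a :class:`PlantedSpec`.

    Returns the network and the planted truth as a ``term -> member set``
    mapping (shaped like a filtered gold standard).  Edges planted by
    several overlapping modules are collapsed keeping the maximum weight.
    Fully reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    net = Network()
    nodes_seen: list = []
    seen = set()
    for mod in spec.modules:
        for u in mod.members:
            if u not in seen:
                seen.add(u)
                nodes_seen.append(u)
    for u in nodes_seen:
        net._intern(u)  # fix node order to first appearance across modules
    for mod in spec.modules:
        for u, v, w in _module_edges(mod, rng):
            net.add_edge(u, v, w)

    n_module_edges = net.n_edges
    n_noise = spec.noise_edges
    if spec.noise_fraction is not None:
        n_noise = int(round(spec.noise_fraction * n_module_edges))
    if n_noise:
        co_module = set()
        for mod in spec.modules:
            ms = list(mod.members)
            for a in range(len(ms)):
                for b in range(a + 1, len(ms)):
                    co_module.add(frozenset((ms[a], ms[b])))
        candidates = [
            (nodes_seen[a], nodes_seen[b])
            for a in range(len(nodes_seen))
            for b in range(a + 1, len(nodes_seen))
            if frozenset((nodes_seen[a], nodes_seen[b])) not in co_module
        ]
        if n_noise > len(candidates):
            raise ValueError(
                f"requested {n_noise} noise edges but only "
                f"{len(candidates)} non-co-module pairs exist"
            )
        picks = rng.choice(len(candidates), size=n_noise, replace=False)
        for idx in sorted(picks):
            u, v = candidates[idx]
            net.add_edge(u, v, spec.noise_weight)

    truth = {
        f"module_{k:03d}": frozenset(mod.members)
        for k, mod in enumerate(spec.modules)
    }
    return net, truth


# ---------------------------------------------------------------------------
# canonical structural fixtures


def bridged_modules_fixture() -> tuple[Network, dict[str, frozenset]]:
    """Two 5-node cliques sharing a single bridge node (9 nodes, bridge degree 8)."""
    a = ("a1", "a2", "a3", "a4", "bridge")
    b = ("bridge", "b1", "b2", "b3", "b4")
    return generate(PlantedSpec(modules=[ModuleSpec(a), ModuleSpec(b)]))


def overlapping_modules_fixture() -> tuple[Network, dict[str, frozenset]]:
    """Two 8-node cliques overlapping in 5 nodes (NA = 25/64 between the truths)."""
    a = tuple(f"v{i}" for i in range(8))
    b = tuple(f"v{i}" for i in range(3, 11))
    return generate(PlantedSpec(modules=[ModuleSpec(a), ModuleSpec(b)]))


def nested_modules_fixture() -> tuple[Network, dict[str, frozenset]]:
    """A 10-node parent module containing two 5-node child cliques.

    Child-internal edges have weight 1; the remaining parent pairs are
    present at weight 0.5, so the parent is a complete graph whose strong
    edges delineate the children.  Truth lists parent and both children.
    """
    child1 = tuple(f"p{i}" for i in range(5))
    child2 = tuple(f"p{i}" for i in range(5, 10))
    parent = child1 + child2
    net, _ = generate(
        PlantedSpec(
            modules=[
                ModuleSpec(parent, weight=0.5),
                ModuleSpec(child1, weight=1.0),
                ModuleSpec(child2, weight=1.0),
            ]
        )
    )
    truth = {
        "parent": frozenset(parent),
        "child_1": frozenset(child1),
        "child_2": frozenset(child2),
    }
    return net, truth


def planted_benchmark(
    n_nodes: int = 200,
    n_modules: int = 20,
    overlap_fraction: float = 0.3,
    noise_fraction: float = 0.05,
    p_in: float = 0.9,
    seed: int = 0,
) -> tuple[Network, dict[str, frozenset]]:
    """A randomized overlapping-module benchmark.

    ``n_nodes`` nodes are partitioned evenly into ``n_modules`` primary
    modules; then ``overlap_fraction`` of the nodes are additionally
    assigned to a second, different module, so that fraction of nodes
    belongs to at least two modules.  Module-internal edges appear with
    probability ``p_in`` (each module is kept connected), and
    ``noise_fraction`` of the realized module-edge count is added as random
    inter-module edges.  Defaults emulate a small interactome region with
    heavy functional overlap and a modest false-positive edge rate.
    """
    if n_nodes < 3 * n_modules:
        raise ValueError("need at least 3 nodes per module")
    rng = np.random.default_rng(seed)
    nodes = [f"v{i:03d}" for i in range(n_nodes)]
    membership: list[list[str]] = [[] for _ in range(n_modules)]
    for i, u in enumerate(nodes):
        membership[i % n_modules].append(u)
    n_overlap = int(round(overlap_fraction * n_nodes))
    primary = {u: i % n_modules for i, u in enumerate(nodes)}
    extra_nodes = rng.choice(n_nodes, size=n_overlap, replace=False)
    for idx in sorted(extra_nodes):
        u = nodes[idx]
        others = [m for m in range(n_modules) if m != primary[u]]
        membership[others[rng.integers(len(others))]].append(u)
    modules = [
        ModuleSpec(tuple(ms), p_in=p_in) for ms in membership if len(ms) >= 3
    ]
    spec = PlantedSpec(
        modules=modules,
        noise_fraction=noise_fraction,
        seed=int(rng.integers(2**31 - 1)),
    )
    return generate(spec)
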