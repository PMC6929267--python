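"""Graph/partition data model and partition quality functions.

The quantities implemented here are the vocabulary of modularity-based
community detection: per-module quality ``Q_m``, partition modularity ``Q``,
the topological qualification test for a subgraph to count as a module, the
resolution-limit scales of modularity optimization, partition density, and
the composite quality score.

All edge-count quantities are computed against the *whole* network with
``L`` total edges: a module's quality depends on the global edge count, not
on the induced subgraph alone.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Hashable, Iterable, Iterator, Mapping

import networkx as nx

logger = logging.getLogger(__name__)

Node = Hashable

__all__ = [
    "Network",
    "Partition",
    "ModuleStats",
    "ModuleDiagnostics",
    "ResolutionLimits",
    "module_stats",
    "modularity",
    "qualifies_as_module",
    "resolution_limits",
    "partition_density",
    "composite_score",
]


class Network:
    """Simple undirected graph with node identifiers as opaque tokens.

    Self-loops and duplicate edges are dropped on construction (a count is
    logged).  ``L`` is the total number of edges, the normalizer of every
    quality function in this package.
    """

    __slots__ = ("graph", "n_selfloops_dropped", "n_duplicates_dropped")

    def __init__(self, edges: Iterable[tuple[Node, Node]] = (),
                 nodes: Iterable[Node] = ()):
        g = nx.Graph()
        g.add_nodes_from(nodes)
        selfloops = 0
        duplicates = 0
        for u, v in edges:
            if u == v:
                selfloops += 1
                g.add_node(u)
            elif g.has_edge(u, v):
                duplicates += 1
            else:
                g.add_edge(u, v)
        self.graph = g
        self.n_selfloops_dropped = selfloops
        self.n_duplicates_dropped = duplicates
        if selfloops or duplicates:
            logger.warning(
                "dropped %d self-loop(s) and %d duplicate edge(s) on construction",
                selfloops, duplicates)

    @classmethod
    def from_graph(cls, g: nx.Graph) -> "Network":
        """Wrap an existing graph, enforcing the simple-graph invariants."""
        net = cls.__new__(cls)
        selfloops = list(nx.selfloop_edges(g))
        if selfloops or g.is_directed() or g.is_multigraph():
            h = nx.Graph()
            h.add_nodes_from(g.nodes())
            h.add_edges_from((u, v) for u, v in g.edges() if u != v)
            net.graph = h
        else:
            net.graph = g
        net.n_selfloops_dropped = len(selfloops)
        net.n_duplicates_dropped = 0
        return net

    @property
    def L(self) -> int:
        return self.graph.number_of_edges()

    @property
    def nodes(self):
        return self.graph.nodes

    def number_of_nodes(self) -> int:
        return self.graph.number_of_nodes()

    def degree(self, node: Node) -> int:
        return self.graph.degree(node)

    def subgraph(self, members: Iterable[Node]) -> "Network":
        """Induced subgraph on ``members`` as a new :class:`Network`."""
        return Network.from_graph(self.graph.subgraph(members).copy())

    def __contains__(self, node: Node) -> bool:
        return node in self.graph

    def __len__(self) -> int:
        return self.graph.number_of_nodes()

    def __repr__(self) -> str:  # pragma: no cover
        return f"Network(n={len(self)}, L={self.L})"


class Partition:
    """Disjoint assignment of every node to exactly one module.

    Stored as a mapping ``node -> module label``; the module view (label ->
    frozen node set) is derived lazily and cached.
    """

    __slots__ = ("assignment", "_modules")

    def __init__(self, assignment: Mapping[Node, Hashable]):
        self.assignment = dict(assignment)
        self._modules: dict[Hashable, frozenset] | None = None

    @classmethod
    def from_modules(cls, modules: Iterable[Iterable[Node]],
                     labels: Iterable[Hashable] | None = None) -> "Partition":
        assignment: dict[Node, Hashable] = {}
        mods = list(modules)
        labs = list(labels) if labels is not None else list(range(len(mods)))
        if len(labs) != len(mods):
            raise ValueError("labels and modules must have equal length")
        if len(set(labs)) != len(labs):
            raise ValueError("module labels must be unique")
        for lab, members in zip(labs, mods):
            for node in members:
                if node in assignment:
                    raise ValueError(f"node {node!r} assigned to two modules")
                assignment[node] = lab
        return cls(assignment)

    @property
    def modules(self) -> dict[Hashable, frozenset]:
        if self._modules is None:
            out: dict[Hashable, set] = {}
            for node, lab in self.assignment.items():
                out.setdefault(lab, set()).add(node)
            self._modules = {lab: frozenset(s) for lab, s in out.items()}
        return self._modules

    def labels(self) -> list[Hashable]:
        return list(self.modules)

    def sizes(self) -> list[int]:
        return [len(m) for m in self.modules.values()]

    def validate(self, network: Network) -> None:
        """Raise ``ValueError`` naming an offending node if invalid."""
        net_nodes = set(network.nodes)
        part_nodes = set(self.assignment)
        missing = net_nodes - part_nodes
        if missing:
            raise ValueError(
                f"node {next(iter(missing))!r} of the network has no module")
        extra = part_nodes - net_nodes
        if extra:
            raise ValueError(
                f"node {next(iter(extra))!r} of the partition is not in the network")

    def relabel(self, mapping: Mapping[Hashable, Hashable]) -> "Partition":
        return Partition({n: mapping.get(l, l) for n, l in self.assignment.items()})

    def __len__(self) -> int:
        return len(self.modules)

    def __eq__(self, other) -> bool:
        if not isinstance(other, Partition):
            return NotImplemented
        return self.assignment == other.assignment

    def __iter__(self) -> Iterator[frozenset]:
        return iter(self.modules.values())

    def __repr__(self) -> str:  # pragma: no cover
        return f"Partition(n_nodes={len(self.assignment)}, n_modules={len(self)})"


@dataclass(frozen=True)
class ModuleStats:
    """Per-module counts entering the module quality.

    ``theta_m = theta_in + theta_out`` with ``theta_in = 2*l_m`` (each
    intra-module edge contributes two internal degree ends) and
    ``theta_out = l_out`` the number of edges leaving the module.  ``a`` is
    the ratio of external to internal edges ``l_out / l_m`` (``nan`` when
    ``l_m = 0``); a module is topologically meaningful only for ``a < 2``.
    """

    n_m: int
    l_m: int
    l_out: int
    Q_m: float
    gamma: float

    @property
    def theta_in(self) -> int:
        return 2 * self.l_m

    @property
    def theta_out(self) -> int:
        return self.l_out

    @property
    def theta_m(self) -> int:
        return 2 * self.l_m + self.l_out

    @property
    def a(self) -> float:
        if self.l_m == 0:
            return math.nan
        return self.l_out / self.l_m


@dataclass(frozen=True)
class ModuleDiagnostics:
    """Outcome of the module qualification test with per-condition detail."""

    qualifies: bool
    positive_quality: bool
    internal_exceeds_external: bool
    stats: ModuleStats


@dataclass(frozen=True)
class ResolutionLimits:
    """Edge-count scales of the resolution limit for a network with L edges.

    ``l_min = sqrt(L/2)`` is the best-case smallest resolvable module scale
    (modules chained by single links); ``l_max = L/4`` is the worst-case
    scale (intra- and inter-module edges balanced).  A module with more than
    ``refinable_threshold = sqrt(2L)`` intra-module edges can contain two or
    more valid sub-modules and is therefore a candidate for refinement.
    """

    L: int
    l_min: float = field(init=False)
    l_max: float = field(init=False)
    refinable_threshold: float = field(init=False)

    def __post_init__(self):
        object.__setattr__(self, "l_min", math.sqrt(self.L / 2.0))
        object.__setattr__(self, "l_max", self.L / 4.0)
        object.__setattr__(self, "refinable_threshold", math.sqrt(2.0 * self.L))


def _check_members(network: Network, members) -> frozenset:
    members = frozenset(members)
    if not members:
        raise ValueError("module member set is empty")
    for node in members:
        if node not in network:
            raise ValueError(f"node {node!r} is not in the network")
    return members


def _edge_counts(network: Network, members: frozenset) -> tuple[int, int]:
    """(intra-module edges, edges to the rest of the network)."""
    g = network.graph
    l_m = 0
    l_out = 0
    for u in members:
        for v in g[u]:
            if v in members:
                l_m += 1  # counted from both ends
            else:
                l_out += 1
    return l_m // 2, l_out


def module_stats(network: Network, members: Iterable[Node],
                 gamma: float = 1.0) -> ModuleStats:
    """Counts and quality ``Q_m = l_m/L - gamma * (theta_m / 2L)**2`` of a module.

    The quality compares the module's intra-module edge fraction with the
    expectation for a degree-preserving random graph, scaled by the
    resolution parameter ``gamma``.
    """
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    members = _check_members(network, members)
    L = network.L
    if L == 0:
        raise ValueError("module quality is undefined on an edgeless network")
    l_m, l_out = _edge_counts(network, members)
    theta_m = 2 * l_m + l_out
    q_m = l_m / L - gamma * (theta_m / (2.0 * L)) ** 2
    return ModuleStats(n_m=len(members), l_m=l_m, l_out=l_out, Q_m=q_m,
                       gamma=gamma)


def modularity(network: Network, partition: Partition,
               gamma: float = 1.0) -> float:
    """Partition modularity: the sum of per-module qualities ``Q_m``."""
    partition.validate(network)
    if network.L == 0:
        raise ValueError("modularity is undefined on an edgeless network")
    return sum(module_stats(network, members, gamma).Q_m
               for members in partition.modules.values())


def qualifies_as_module(network: Network, members: Iterable[Node],
                        gamma: float = 1.0) -> ModuleDiagnostics:
    """Topological qualification test for a subgraph to count as a module.

    Two conditions, both strict: the module quality must be positive
    (``Q_m > 0`` at the working ``gamma``) and the internal degree sum must
    exceed the external one (``theta_in > theta_out``, equivalently
    ``a < 2``, which also implies ``l_m < L/4`` whenever ``Q_m > 0``).
    """
    stats = module_stats(network, members, gamma)
    positive = stats.Q_m > 0.0
    internal = stats.theta_in > stats.theta_out
    return ModuleDiagnostics(qualifies=positive and internal,
                             positive_quality=positive,
                             internal_exceeds_external=internal,
                             stats=stats)


def resolution_limits(L: int) -> ResolutionLimits:
    """Resolution-limit scales for a network with ``L`` edges."""
    if L < 1:
        raise ValueError("L must be a positive integer")
    return ResolutionLimits(L=int(L))


def partition_density(network: Network, partition: Partition) -> float:
    """Partition density: link densities of modules, edge-weighted.

    ``PD = (1/L) * sum_m l_m * (l_m - (n_m - 1)) / (n_m(n_m-1)/2 - (n_m-1))``

    Each module contributes its intra-module edge count times its normalized
    link density (0 for a spanning tree, 1 for a clique).  Modules with two
    or fewer nodes contribute 0: the density denominator vanishes at
    ``n_m = 2`` and link density is undefined below three nodes.  PD does
    not suffer from the resolution limit and is at most 1, with equality iff
    every module is a clique of at least three nodes and no inter-module
    edges exist.
    """
    partition.validate(network)
    L = network.L
    if L == 0:
        raise ValueError("partition density is undefined on an edgeless network")
    total = 0.0
    for members in partition.modules.values():
        n_m = len(members)
        if n_m <= 2:
            continue
        l_m, _ = _edge_counts(network, members)
        denom = n_m * (n_m - 1) / 2.0 - (n_m - 1)
        total += l_m * (l_m - (n_m - 1)) / denom
    return total / L


def composite_score(Q: float, PD: float) -> float:
    """Composite partition quality: modularity plus partition density.

    Combines the global (modularity) and local, resolution-limit-free
    (partition density) views of quality; both terms are bounded by 1 and
    the score is used ordinally — higher is better.
    """
    return Q + PD
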