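"""Iterative re-modularization of refinable modules under topological constraints.

Modularity maximization has a resolution limit: modules with fewer than
about ``sqrt(L/2)`` intra-module edges cannot be resolved, so optimal
partitions of large networks hide small communities inside super-modules.
The refinement algorithm trades a bounded amount of modularity for
resolution: starting from a modularity-maximizing partition it repeatedly

1. selects a *refinable* module — one with more than ``sqrt(2L)``
   intra-module edges, hence large enough to club two or more valid
   sub-modules;
2. re-modularizes it as an individual graph with the configured detector;
3. filters the sub-modules by the topological qualification test
   (``Q_m > 0`` and internal degree sum > external degree sum, both
   evaluated in the parent module's induced graph, i.e. with respect to the
   sibling sub-modules); sub-modules that fail are regrouped into a single
   set;
4. re-submits accepted sub-modules and the regrouped remainder to step 1.

The loop stops when no refinable module is left, when the cumulative
modularity loss relative to the input partition would exceed the budget
``rho`` (the offending split is reverted and that module frozen), or at a
safety cap on rounds.
"""

from __future__ import annotations

import logging
import math
import random
from dataclasses import dataclass, field
from typing import Hashable, Iterable

from .core import (Network, Partition, module_stats, modularity,
                   qualifies_as_module)
from .detectors import DetectorSpec, detect

logger = logging.getLogger(__name__)

__all__ = [
    "RefinementConfig",
    "RefinementResult",
    "is_refinable",
    "split_module",
    "filter_submodules",
    "refine",
]


@dataclass(frozen=True)
class RefinementConfig:
    """Parameters of a refinement run.

    ``rho`` is the modularity-loss budget: the refined partition's
    modularity never drops more than ``rho`` below the input partition's.
    When unset it defaults to ``0.2 * Q_init``, a scale-free relative
    budget.  ``detector`` performs the incremental re-modularization of each
    refinable module; ``seed`` makes the whole run deterministic.
    """

    gamma: float = 1.0
    rho: float | None = None
    detector: DetectorSpec = field(default_factory=DetectorSpec)
    max_rounds: int = 10_000
    seed: int | None = None

    def __post_init__(self):
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.rho is not None and self.rho < 0:
            raise ValueError("rho must be non-negative")
        if self.max_rounds < 1:
            raise ValueError("max_rounds must be at least 1")


@dataclass
class RefinementResult:
    """Final partition of a refinement run plus its provenance.

    ``genealogy`` maps each final module label to the chain of ancestor
    labels back to the input partition (child labels extend the parent's
    with ``.i`` suffixes); every final module's node set is a subset of its
    root ancestor's.
    """

    partition: Partition
    Q_init: float
    Q_final: float
    genealogy: dict[Hashable, tuple[Hashable, ...]]
    n_refinable_initial: int
    rounds: int
    converged_by: str
    rho: float

    @property
    def modularity_loss(self) -> float:
        return self.Q_init - self.Q_final


def is_refinable(network: Network, members: Iterable) -> bool:
    """True iff the module has more than ``sqrt(2L)`` intra-module edges.

    ``L`` is the global edge count of the original network; such a module is
    large enough, by the resolution-limit argument, to contain two or more
    valid sub-modules.
    """
    members = frozenset(members)
    if not members:
        return False
    l_m = network.subgraph(members).L
    return l_m > math.sqrt(2.0 * network.L)


def split_module(network: Network, members: Iterable,
                 config: RefinementConfig) -> list[frozenset]:
    """Re-modularize a module as an individual graph.

    Runs the configured detector on the subgraph induced by ``members`` and
    returns the resulting sub-module node sets (a partition of ``members``).
    """
    members = frozenset(members)
    if not members:
        raise ValueError("cannot split an empty module")
    sub = network.subgraph(members)
    spec = DetectorSpec(config.detector.method, config.gamma,
                        config.detector.seed if config.seed is None
                        else config.seed)
    part = detect(sub, spec)
    return [frozenset(m) for m in part.modules.values()]


def filter_submodules(network: Network, submodules: Iterable[Iterable],
                      gamma: float = 1.0
                      ) -> tuple[list[frozenset], frozenset]:
    """Split sub-modules into those that qualify and a regrouped remainder.

    Each sub-module is tested with the topological qualification criteria
    (``Q_m > 0`` and internal degree sum > external degree sum) against the
    graph ``network`` it was detected in.  During refinement that graph is
    the parent module re-modularized as an individual graph, so external
    degrees are counted with respect to the sibling sub-modules — the only
    reading under which communities of networks with mixing above 0.5 can
    qualify at all.  The failing sub-modules are merged into a single node
    set (empty when all pass).
    """
    accepted: list[frozenset] = []
    rejected: set = set()
    for sm in submodules:
        sm = frozenset(sm)
        if not sm:
            continue
        if qualifies_as_module(network, sm, gamma).qualifies:
            accepted.append(sm)
        else:
            rejected.update(sm)
    return accepted, frozenset(rejected)


def _intra_edges(network: Network, members: frozenset) -> int:
    g = network.graph
    return sum(1 for u in members for v in g[u] if v in members) // 2


def refine(network: Network, initial: Partition,
           config: RefinementConfig | None = None) -> RefinementResult:
    """Refine a partition by iterative re-modularization of its large modules.

    Non-refinable modules pass through untouched.  Each round pops the
    refinable module with the most intra-module edges (largest-first, so the
    biggest quality losses are charged against the budget first and the run
    is deterministic), splits it, filters the sub-modules, and re-enqueues
    accepted sub-modules and the regrouped remainder if they are themselves
    refinable.  A round whose cumulative modularity loss would exceed
    ``rho`` is reverted and its module frozen.
    """
    if config is None:
        config = RefinementConfig()
    initial.validate(network)
    if network.L == 0:
        raise ValueError("cannot refine a partition of an edgeless network")

    gamma = config.gamma
    q_init = modularity(network, initial, gamma)
    rho = config.rho if config.rho is not None else 0.2 * abs(q_init)
    threshold = math.sqrt(2.0 * network.L)
    rng = random.Random(config.seed)

    current: dict[Hashable, frozenset] = dict(initial.modules)
    genealogy: dict[Hashable, tuple[Hashable, ...]] = {
        lab: (lab,) for lab in current}
    quality: dict[Hashable, float] = {
        lab: module_stats(network, mem, gamma).Q_m
        for lab, mem in current.items()}

    def l_m(label: Hashable) -> int:
        return _intra_edges(network, current[label])

    queue: dict[Hashable, int] = {
        lab: lm for lab in current if (lm := l_m(lab)) > threshold}
    n_refinable_initial = len(queue)

    q_current = q_init
    cum_loss = 0.0
    rounds = 0
    budget_hit = False
    frozen: set[Hashable] = set()

    while queue and rounds < config.max_rounds:
        label = max(queue, key=lambda lab: (queue[lab], str(lab)))
        lm = queue.pop(label)
        members = current[label]

        split_seed = rng.randrange(2**31) if config.seed is not None else None
        parent = network.subgraph(members)
        spec = DetectorSpec(config.detector.method, gamma, split_seed)
        submodules = [frozenset(m) for m in detect(parent, spec).modules.values()]
        rounds += 1

        if len(submodules) == 1:
            # no internal structure found; mark non-refinable to guarantee progress
            frozen.add(label)
            continue

        accepted, rejected = filter_submodules(parent, submodules, gamma)
        if not accepted or rejected == members:
            frozen.add(label)
            continue

        pieces = list(accepted) + ([rejected] if rejected else [])
        new_qualities = [module_stats(network, p, gamma).Q_m for p in pieces]
        delta = sum(new_qualities) - quality[label]
        # the budget meters accumulated losses; windfall gains from splitting
        # a badly merged module do not enlarge it
        if delta < 0 and cum_loss - delta > rho:
            budget_hit = True
            frozen.add(label)
            logger.info("round %d: reverting split of %r (cumulative loss "
                        "%.4f would exceed budget %.4f)", rounds, label,
                        cum_loss - delta, rho)
            continue
        if delta < 0:
            cum_loss -= delta

        parent_chain = genealogy.pop(label)
        del current[label], quality[label]
        for i, (piece, q_piece) in enumerate(zip(pieces, new_qualities)):
            child = f"{parent_chain[-1]}.{i}"
            while child in current:  # guard against label collisions
                child += "'"
            current[child] = piece
            quality[child] = q_piece
            genealogy[child] = parent_chain + (child,)
            lm_child = _intra_edges(network, piece)
            if lm_child > threshold:
                queue[child] = lm_child
        q_current += delta
        logger.info("round %d: module %r (l_m=%d) -> %d sub-module(s), "
                    "dQ=%.4f, cumulative loss %.4f", rounds, label, lm,
                    len(pieces), delta, q_init - q_current)

    if rounds >= config.max_rounds and queue:
        converged_by = "max_rounds"
    elif budget_hit:
        converged_by = "loss_budget"
    else:
        converged_by = "no_refinable_left"

    final = Partition.from_modules(current.values(), labels=list(current))
    return RefinementResult(partition=final, Q_init=q_init,
                            Q_final=modularity(network, final, gamma),
                            genealogy=dict(genealogy),
                            n_refinable_initial=n_refinable_initial,
                            rounds=rounds, converged_by=converged_by, rho=rho)
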