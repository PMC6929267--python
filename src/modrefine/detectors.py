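"""Pluggable community-detection backends.

The refinement engine only depends on the :func:`detect` contract — any
algorithm that maps a network to a partition can serve as the initial
modularizer or the incremental re-modularizer.  Three backends are bundled,
all delegating to networkx: Louvain (stochastic, seeded, gamma-aware),
Clauset–Newman–Moore greedy modularity (deterministic, gamma-aware) and
asynchronous label propagation (stochastic, ignores gamma).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from .core import Network, Partition

__all__ = ["DetectorSpec", "detect", "SUPPORTED_METHODS"]

SUPPORTED_METHODS = ("louvain", "greedy", "label_propagation")


@dataclass(frozen=True)
class DetectorSpec:
    """Configuration of a detection backend.

    ``gamma`` is the resolution parameter of the modularity being optimized
    (ignored by label propagation); ``seed`` fixes the stochastic backends
    so that repeated calls return identical partitions.
    """

    method: str = "louvain"
    gamma: float = 1.0
    seed: int | None = None

    def __post_init__(self):
        if self.method not in SUPPORTED_METHODS:
            raise ValueError(
                f"unsupported detector {self.method!r}; "
                f"choose one of {SUPPORTED_METHODS}")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")

    def with_seed(self, seed: int | None) -> "DetectorSpec":
        return DetectorSpec(self.method, self.gamma, seed)


def detect(network: Network, spec: DetectorSpec) -> Partition:
    """Run the configured backend and return a partition of all nodes.

    Disconnected networks are allowed.  On an edgeless network every backend
    returns the all-singletons partition (there is nothing to optimize).
    """
    if network.number_of_nodes() == 0:
        raise ValueError("cannot detect communities in an empty network")
    g = network.graph
    if network.L == 0:
        communities = [{v} for v in g]
    elif spec.method == "louvain":
        communities = nx.community.louvain_communities(
            g, resolution=spec.gamma, seed=spec.seed)
    elif spec.method == "greedy":
        communities = nx.community.greedy_modularity_communities(
            g, resolution=spec.gamma)
    else:  # label_propagation
        communities = nx.community.asyn_lpa_communities(g, seed=spec.seed)
    return Partition.from_modules(communities)
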