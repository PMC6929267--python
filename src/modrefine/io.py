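"""Edge-list and partition readers/writers.

Edge lists are whitespace- or tab-delimited two-column files (a third
weight column is ignored with a warning, as all quality functions here are
unweighted); partitions are tab-delimited (node, module label) tables.
Lines starting with ``#`` are comments.
"""

from __future__ import annotations

import logging
from pathlib import Path

from .core import Network, Partition

logger = logging.getLogger(__name__)

__all__ = ["read_edge_list", "write_edge_list",
           "read_partition", "write_partition"]


def read_edge_list(path) -> Network:
    """Read a network from a delimited edge list.

    Node identifiers are opaque case-sensitive tokens; self-loops and
    duplicate edges are dropped (with logged counts) per the simple-graph
    construction rules.
    """
    edges = []
    weight_seen = False
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(
                    f"{path}:{ln}: malformed edge line {line!r} "
                    "(need two node columns)")
            if len(parts) >= 3 and not weight_seen:
                weight_seen = True
                logger.warning("%s:%d: third column ignored (networks are "
                               "unweighted)", path, ln)
            edges.append((parts[0], parts[1]))
    return Network(edges)


def write_edge_list(network: Network, path, header: str | None = None) -> None:
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        for u, v in network.graph.edges():
            fh.write(f"{u}\t{v}\n")


def write_partition(partition: Partition, path,
                    header: str | None = None) -> None:
    """Write a partition as tab-delimited (node, module label) rows."""
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        for node, label in partition.assignment.items():
            fh.write(f"{node}\t{label}\n")


def read_partition(path) -> Partition:
    """Read a tab-delimited (node, module label) partition table."""
    assignment = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2 or not parts[1]:
                raise ValueError(
                    f"{path}:{ln}: node {parts[0]!r} is missing a module label")
            node, label = parts[0], parts[1]
            if node in assignment:
                raise ValueError(f"{path}:{ln}: node {node!r} listed twice")
            assignment[node] = label
    if not assignment:
        raise ValueError(f"{path}: empty partition file")
    return Partition(assignment)
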