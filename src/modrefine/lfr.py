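"""LFR-style benchmark graphs with planted communities.

Generates networks with power-law degree and community-size distributions
and a planted partition, the standard testbed for community detection.
Construction follows the original recipe: every node's degree is split into
an internal part ``(1 - mu) * d`` wired inside its community and an external
part ``mu * d`` wired between communities, each realized by a
configuration-model pairing that is rewired until the graph is simple (and,
for the external part, free of intra-community edges).  The mixing
parameter ``mu`` — the fraction of each node's edges that leave its planted
community — is therefore realized per node up to integer rounding.
"""

from __future__ import annotations

import networkx as nx
import numpy as np

__all__ = ["lfr_graph", "LFRGenerationError"]


class LFRGenerationError(RuntimeError):
    """Raised when a benchmark graph cannot be realized for the parameters."""


def _powerlaw_pmf(exponent: float, lo: int, hi: int):
    ks = np.arange(lo, hi + 1, dtype=np.int64)
    w = ks.astype(float) ** (-exponent)
    return ks, w / w.sum()


def _powerlaw_mean(exponent: float, lo: int, hi: int) -> float:
    ks, p = _powerlaw_pmf(exponent, lo, hi)
    return float(np.dot(ks, p))


def _sample_degrees(n: int, avg_degree: float, max_degree: int,
                    exponent: float, rng: np.random.Generator) -> np.ndarray:
    """Power-law degrees with the requested expected mean.

    The integer lower cutoff is chosen so the truncated power law brackets
    ``avg_degree``; nodes are sampled from a mixture of the two bracketing
    cutoffs so the expectation matches exactly.
    """
    if _powerlaw_mean(exponent, 1, max_degree) > avg_degree:
        lo = 1
        frac_hi = 0.0
    else:
        lo = 1
        while lo < max_degree and _powerlaw_mean(exponent, lo + 1,
                                                 max_degree) <= avg_degree:
            lo += 1
        m_lo = _powerlaw_mean(exponent, lo, max_degree)
        m_hi = _powerlaw_mean(exponent, min(lo + 1, max_degree), max_degree)
        frac_hi = 0.0 if m_hi <= m_lo else (avg_degree - m_lo) / (m_hi - m_lo)
    use_hi = rng.random(n) < frac_hi
    ks_lo, p_lo = _powerlaw_pmf(exponent, lo, max_degree)
    degrees = rng.choice(ks_lo, size=n, p=p_lo)
    n_hi = int(use_hi.sum())
    if n_hi and lo + 1 <= max_degree:
        ks_hi, p_hi = _powerlaw_pmf(exponent, lo + 1, max_degree)
        degrees[use_hi] = rng.choice(ks_hi, size=n_hi, p=p_hi)
    return degrees.astype(np.int64)


def _sample_community_sizes(n: int, min_size: int, max_size: int,
                            exponent: float,
                            rng: np.random.Generator) -> list[int]:
    """Power-law community sizes summing exactly to ``n``."""
    ks, p = _powerlaw_pmf(exponent, min_size, max_size)
    sizes: list[int] = []
    while sum(sizes) < n:
        sizes.append(int(rng.choice(ks, p=p)))
    excess = sum(sizes) - n
    # shave the excess off communities that are above the minimum
    i = 0
    guard = 0
    while excess > 0:
        if sizes[i % len(sizes)] > min_size:
            sizes[i % len(sizes)] -= 1
            excess -= 1
        i += 1
        guard += 1
        if guard > 100 * len(sizes) + excess:
            # all at the minimum: drop one community, top up the others
            sizes.pop()
            deficit = n - sum(sizes)
            j = 0
            while deficit > 0 and j < 10 * len(sizes):
                if sizes[j % len(sizes)] < max_size:
                    sizes[j % len(sizes)] += 1
                    deficit -= 1
                j += 1
            if deficit != 0:
                raise LFRGenerationError(
                    f"cannot realize community sizes summing to {n} in "
                    f"[{min_size}, {max_size}]")
            excess = 0
    return sizes


def _assign_communities(int_deg: np.ndarray, sizes: list[int],
                        rng: np.random.Generator) -> np.ndarray:
    """Assign nodes to communities so each fits (internal degree < size).

    Nodes are placed in decreasing order of internal degree into a random
    community that still has room and is large enough; if none is large
    enough the node's internal degree is capped to the largest remaining
    community (the surplus becomes external edges).
    """
    n = len(int_deg)
    order = np.argsort(-int_deg, kind="stable")
    capacity = np.array(sizes, dtype=np.int64)
    size_arr = np.array(sizes, dtype=np.int64)
    membership = np.full(n, -1, dtype=np.int64)
    for node in order:
        d_in = int_deg[node]
        eligible = np.flatnonzero((capacity > 0) & (size_arr - 1 >= d_in))
        if len(eligible) == 0:
            open_comms = np.flatnonzero(capacity > 0)
            if len(open_comms) == 0:
                raise LFRGenerationError("community capacities exhausted")
            # cap the internal degree to what the biggest open community allows
            c = open_comms[np.argmax(size_arr[open_comms])]
            int_deg[node] = size_arr[c] - 1
        else:
            # weight by free slots so hubs do not pile into small communities
            w = capacity[eligible].astype(float)
            c = rng.choice(eligible, p=w / w.sum())
        membership[node] = c
        capacity[c] -= 1
    return membership


def _repair_pairing(pairs: list[list[int]], allowed, rng: np.random.Generator,
                    max_sweeps: int = 60) -> bool:
    """Rewire a stub pairing until every pair satisfies ``allowed``.

    Violating pairs (self-loops, duplicates, pairs failing ``allowed``)
    exchange endpoints with randomly chosen other pairs; the degree sequence
    is preserved by construction.  Returns False if violations remain after
    the sweep budget.
    """
    def key(u, v):
        return (u, v) if u <= v else (v, u)

    def scan():
        edge_set: set[tuple[int, int]] = set()
        bad: list[int] = []
        for i, (u, v) in enumerate(pairs):
            k = key(u, v)
            if not allowed(u, v) or k in edge_set:
                bad.append(i)
            else:
                edge_set.add(k)
        return edge_set, bad

    n_pairs = len(pairs)
    for _ in range(max_sweeps):
        edge_set, bad = scan()
        if not bad:
            return True
        for i in bad:
            u1, v1 = pairs[i]
            for j in rng.integers(0, n_pairs, size=12):
                j = int(j)
                if j == i:
                    continue
                u2, v2 = pairs[j]
                kj = key(u2, v2)
                done = False
                for a, b, c, d in ((u1, v2, u2, v1), (u1, u2, v1, v2)):
                    ka, kc = key(a, b), key(c, d)
                    if (allowed(a, b) and allowed(c, d) and ka != kc
                            and ka not in edge_set and kc not in edge_set):
                        edge_set.discard(kj)
                        pairs[i] = [a, b]
                        pairs[j] = [c, d]
                        edge_set.add(ka)
                        edge_set.add(kc)
                        done = True
                        break
                if done:
                    break
    _, bad = scan()
    return not bad


def _realize_community(members: np.ndarray, degs: np.ndarray,
                       int_deg: np.ndarray,
                       rng: np.random.Generator) -> list[tuple[int, int]]:
    """Wire one community: exact-degree construction, then randomization.

    The internal degree sequence is first repaired to graphicality by
    shaving stubs off the largest-degree members (the shaved stubs become
    external edges), realized by Havel–Hakimi, then randomized with double
    edge swaps so the community is a uniform-ish simple graph with the
    prescribed internal degrees.
    """
    seq = degs.copy()
    while seq.sum() % 2 == 1 or (seq.sum() > 0 and not nx.is_graphical(seq.tolist())):
        top = int(np.argmax(seq))
        seq[top] -= 1
        int_deg[members[top]] -= 1
    if seq.sum() == 0:
        return []
    g = nx.havel_hakimi_graph(seq.tolist())
    edges = [[int(u), int(v)] for u, v in g.edges()]
    n_edges = len(edges)
    if n_edges >= 2:
        edge_set = {(min(u, v), max(u, v)) for u, v in edges}
        idx = rng.integers(0, n_edges, size=(10 * n_edges, 2))
        flips = rng.random(10 * n_edges) < 0.5
        for (i, j), flip in zip(idx, flips):
            if i == j:
                continue
            u1, v1 = edges[i]
            u2, v2 = edges[j]
            a, b, c, d = (u1, v2, u2, v1) if flip else (u1, u2, v1, v2)
            ka = (min(a, b), max(a, b))
            kc = (min(c, d), max(c, d))
            if a == b or c == d or ka == kc or ka in edge_set or kc in edge_set:
                continue
            edge_set.discard((min(u1, v1), max(u1, v1)))
            edge_set.discard((min(u2, v2), max(u2, v2)))
            edge_set.add(ka)
            edge_set.add(kc)
            edges[i] = [a, b]
            edges[j] = [c, d]
    return [(int(members[u]), int(members[v])) for u, v in edges]


def _pair_stubs(stubs: np.ndarray, allowed, rng: np.random.Generator,
                n_attempts: int = 8) -> list[tuple[int, int]] | None:
    for _ in range(n_attempts):
        perm = rng.permutation(len(stubs))
        shuffled = stubs[perm]
        pairs = [[int(shuffled[2 * i]), int(shuffled[2 * i + 1])]
                 for i in range(len(stubs) // 2)]
        if _repair_pairing(pairs, allowed, rng):
            return [(u, v) for u, v in pairs]
    return None


def lfr_graph(n: int, avg_degree: float, max_degree: int,
              min_community: int, max_community: int, mu: float,
              degree_exponent: float = 2.0,
              community_exponent: float = 2.0,
              rng: np.random.Generator | None = None
              ) -> tuple[list[tuple[int, int]], np.ndarray]:
    """Generate one benchmark graph.

    Returns ``(edges, membership)`` where ``membership[i]`` is the planted
    community index of node ``i`` (nodes are ``0..n-1``).

    Raises
    ------
    LFRGenerationError
        if a simple graph realizing the constraints cannot be built.
    """
    if not 0.0 < mu < 1.0:
        raise ValueError("mu must be in (0, 1)")
    if min_community > max_community:
        raise ValueError("min_community must not exceed max_community")
    if degree_exponent <= 1 or community_exponent <= 1:
        raise ValueError("power-law exponents must exceed 1")
    if rng is None:
        rng = np.random.default_rng()

    degrees = _sample_degrees(n, avg_degree, max_degree, degree_exponent, rng)
    sizes = _sample_community_sizes(n, min_community, max_community,
                                    community_exponent, rng)
    int_deg = np.rint((1.0 - mu) * degrees).astype(np.int64)
    membership = _assign_communities(int_deg, sizes, rng)

    edges: list[tuple[int, int]] = []
    for c in range(len(sizes)):
        members = np.flatnonzero(membership == c)
        if len(members) == 0:
            continue
        edges.extend(_realize_community(members, int_deg[members],
                                        int_deg, rng))

    ext_deg = degrees - int_deg
    if int(ext_deg.sum()) % 2 == 1:
        node = int(np.argmax(ext_deg))
        ext_deg[node] -= 1

    ext_stubs = np.repeat(np.arange(n), ext_deg)
    if len(ext_stubs):
        def ext_allowed(u, v):
            return u != v and membership[u] != membership[v]

        pairs = _pair_stubs(ext_stubs, ext_allowed, rng)
        if pairs is None:
            raise LFRGenerationError(
                "could not wire the inter-community graph as a simple graph")
        edges.extend(pairs)

    return edges, membership
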