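"""Functional validation of modules against gene annotations and gene sets.

Hypergeometric enrichment of each module against a gene-to-term annotation
table, a partition-level enrichment-fraction summary over meso-modules
(more than 10 genes), and functional coverage of known gene-set collections
by Jaccard overlap.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import hypergeom

from .core import Partition

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSetCollection",
    "AnnotationTable",
    "TermResult",
    "ModuleEnrichment",
    "enrich_module",
    "enrichment_fraction_summary",
    "functional_coverage",
    "generate_synthetic_annotations",
    "read_gmt",
    "read_annotations",
]

TOP_K = 10


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT-style), optionally with an explicit universe."""

    sets: dict[str, frozenset]
    universe: frozenset | None = None

    def __post_init__(self):
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)


class AnnotationTable:
    """Gene-to-term annotations with a derived term-to-gene index."""

    def __init__(self, gene_terms: dict[str, frozenset]):
        self.gene_terms = {g: frozenset(t) for g, t in gene_terms.items()}
        for gene, terms in self.gene_terms.items():
            if not terms:
                raise ValueError(f"gene {gene!r} has no annotated terms")
        index: dict[str, set] = {}
        for gene, terms in self.gene_terms.items():
            for t in terms:
                index.setdefault(t, set()).add(gene)
        self.term_genes = {t: frozenset(g) for t, g in index.items()}

    @property
    def genes(self) -> frozenset:
        return frozenset(self.gene_terms)

    def __len__(self) -> int:
        return len(self.gene_terms)


@dataclass(frozen=True)
class TermResult:
    term: str
    p_value: float
    k_overlap: int
    term_size: int


@dataclass
class ModuleEnrichment:
    """Enrichment outcome for one module."""

    module: object
    terms: list[TermResult]        # significant terms, p ascending
    top_terms: list[TermResult]    # at most TOP_K of them
    enriched_fraction: float       # module genes annotated to >= 1 top term


def _hypergeom_p(universe_size: int, term_size: int, module_size: int,
                 overlap: int) -> float:
    """One-sided tail P(X >= overlap) for the term/module overlap."""
    return float(hypergeom.sf(overlap - 1, universe_size, term_size,
                              module_size))


def enrich_module(members, annotations: AnnotationTable, universe,
                  alpha: float = 0.05, module_label=None,
                  adjust: bool = False) -> ModuleEnrichment:
    """Hypergeometric over-representation test of a module against all terms.

    For each term the one-sided tail probability of observing at least the
    realized overlap is computed from a hypergeometric draw of
    ``|members|`` genes out of ``|universe|``.  Terms with p below ``alpha``
    (Benjamini–Hochberg-adjusted when ``adjust``) are ranked ascending and
    the top ten retained; the enriched fraction is the share of module
    genes annotated to at least one retained term.
    """
    members = frozenset(members)
    universe = frozenset(universe)
    if not members:
        raise ValueError("module is empty")
    if not universe:
        raise ValueError("universe is empty")
    if not members <= universe:
        raise ValueError("module members must be a subset of the universe")
    results = []
    for term, term_genes in annotations.term_genes.items():
        tg = term_genes & universe
        k = len(members & tg)
        if k == 0:
            continue
        p = _hypergeom_p(len(universe), len(tg), len(members), k)
        results.append(TermResult(term=term, p_value=p, k_overlap=k,
                                  term_size=len(tg)))
    results.sort(key=lambda r: (r.p_value, r.term))
    if adjust and results:
        m = len(annotations.term_genes)
        adj = []
        running_min = 1.0
        for rank, r in enumerate(reversed(results)):
            i = len(results) - rank
            running_min = min(running_min, r.p_value * m / i)
            adj.append(TermResult(r.term, min(running_min, 1.0),
                                  r.k_overlap, r.term_size))
        results = list(reversed(adj))
    significant = [r for r in results if r.p_value < alpha]
    top = significant[:TOP_K]
    covered = set()
    for r in top:
        covered |= annotations.term_genes[r.term] & members
    frac = len(covered) / len(members)
    return ModuleEnrichment(module=module_label, terms=significant,
                            top_terms=top, enriched_fraction=frac)


def enrichment_fraction_summary(partition: Partition,
                                annotations: AnnotationTable,
                                universe=None, alpha: float = 0.05,
                                min_size: int = 11,
                                adjust: bool = False) -> float:
    """Mean enriched fraction over meso-modules (size >= ``min_size``).

    Small modules are excluded: enrichment fractions are only meaningful at
    the meso scale (more than 10 genes).  Returns 0 with a warning when no
    module qualifies.
    """
    if universe is None:
        universe = annotations.genes & frozenset(partition.assignment)
        if not universe:
            universe = annotations.genes
    universe = frozenset(universe)
    fractions = []
    for label, members in partition.modules.items():
        if len(members) < min_size:
            continue
        members_in = members & universe
        if not members_in:
            fractions.append(0.0)
            continue
        enr = enrich_module(members_in, annotations, universe, alpha,
                            module_label=label, adjust=adjust)
        # fraction is over the whole module, unannotated genes included
        fractions.append(enr.enriched_fraction * len(members_in) / len(members))
    if not fractions:
        warnings.warn(f"no module of size >= {min_size}; "
                      "enrichment fraction summary defined as 0")
        return 0.0
    return float(np.mean(fractions))


def functional_coverage(partition: Partition,
                        gene_sets: GeneSetCollection,
                        restrict_to_network: bool = False) -> float:
    """Mean best Jaccard overlap of known gene sets with predicted modules.

    For every gene set the best-matching module (maximum Jaccard
    coefficient) is found; the coverage is the mean of these maxima.  With
    ``restrict_to_network`` gene sets are first intersected with the
    partitioned node set.
    """
    if not gene_sets.sets:
        raise ValueError("gene-set collection is empty")
    modules = list(partition.modules.values())
    nodes = frozenset(partition.assignment)
    best_vals = []
    for genes in gene_sets.sets.values():
        if restrict_to_network:
            genes = genes & nodes
        if not genes:
            best_vals.append(0.0)
            continue
        best = 0.0
        for m in modules:
            inter = len(genes & m)
            if inter:
                best = max(best, inter / len(genes | m))
        best_vals.append(best)
    return float(np.mean(best_vals))


def generate_synthetic_annotations(partition: Partition, n_terms: int,
                                   coherence: float,
                                   seed: int | None = None
                                   ) -> AnnotationTable:
    """Synthetic gene-to-term table with module-coherent signal.

    Every module is assigned a designated term (cyclically from ``n_terms``
    terms); each gene receives its module's term with probability
    ``coherence`` and a uniformly random term otherwise.  A fixture
    generator: with coherence 1 every module is perfectly enriched in its
    own term, with coherence 0 term membership is uniform noise.
    """
    if not 0.0 <= coherence <= 1.0:
        raise ValueError("coherence must be in [0, 1]")
    if n_terms < 1:
        raise ValueError("n_terms must be positive")
    rng = np.random.default_rng(seed)
    terms = [f"T{i:04d}" for i in range(n_terms)]
    module_term = {label: terms[i % n_terms]
                   for i, label in enumerate(sorted(partition.modules,
                                                    key=repr))}
    table: dict[str, frozenset] = {}
    for label, members in sorted(partition.modules.items(),
                                 key=lambda kv: repr(kv[0])):
        for gene in sorted(members, key=repr):
            if rng.random() < coherence:
                term = module_term[label]
            else:
                term = terms[int(rng.integers(n_terms))]
            table[str(gene)] = frozenset({term})
    return AnnotationTable(table)


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file (tab-delimited: name, description, genes...)."""
    sets: dict[str, frozenset] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"{path}:{ln}: GMT line needs name, description and at "
                    "least one gene")
            name = parts[0]
            if name in sets:
                raise ValueError(f"{path}:{ln}: duplicate gene set {name!r}")
            genes = frozenset(g for g in parts[2:] if g)
            if not genes:
                raise ValueError(f"{path}:{ln}: gene set {name!r} is empty")
            sets[name] = genes
    return GeneSetCollection(sets=sets)


def read_annotations(path, delimiter: str | None = None) -> AnnotationTable:
    """Read a two-column gene/term table (whitespace- or tab-delimited)."""
    table: dict[str, set] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(delimiter) if delimiter else line.split()
            if len(parts) < 2:
                raise ValueError(
                    f"{path}:{ln}: expected gene and term columns")
            gene, term = parts[0], parts[1]
            table.setdefault(gene, set()).add(term)
    if not table:
        raise ValueError(f"{path}: no annotations found")
    return AnnotationTable({g: frozenset(t) for g, t in table.items()})
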