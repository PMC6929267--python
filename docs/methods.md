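# Methods

## Quality functions

For a simple undirected network with `L` edges, each module `m` with `n_m`
nodes, `l_m` intra-module edges and total degree `θ_m = 2 l_m + l_out` has
quality

    Q_m = l_m / L − γ (θ_m / 2L)²,

and a partition's modularity is the sum of its modules' qualities. γ > 0 is
the resolution parameter; γ = 1 recovers classical modularity, larger γ
favours smaller modules. A subgraph *qualifies* as a module when both
`Q_m > 0` and `θ_in > θ_out` hold strictly (`θ_in = 2 l_m`,
`θ_out = l_out`; equivalently the external/internal edge ratio
`a = l_out / l_m < 2`). The qualification test uses the same γ as the
quality being optimized — the filter must be consistent with the objective —
although the classical positivity condition is usually written at γ = 1.

Resolution-limit scales for a network with `L` edges: `l_min = √(L/2)`
(best case, modules chained by single links), `l_max = L/4` (worst case,
intra- and inter-module edges balanced). A module with more than
`√(2L)` intra-module edges can contain two or more valid sub-modules and is
called *refinable*.

**Partition density** is the edge-weighted mean of the modules' normalized
link densities:

    PD = (1/L) Σ_m l_m · (l_m − (n_m − 1)) / (n_m(n_m−1)/2 − (n_m − 1)).

Both occurrences of the module edge count in the summand are the same
quantity `l_m` (weight and density numerator). Modules with `n_m ≤ 2`
contribute zero: the denominator vanishes at `n_m = 2` and link density is
undefined below three nodes, so the conservative convention is used.
PD ≤ 1 always, with equality exactly for partitions into cliques of at least
three nodes with no inter-module edges. The **composite score** is `Q + PD`;
no particular combination rule is canonical, and since both terms are
bounded by 1 and the score is only used ordinally, the sum is the simplest
strictly-monotone choice.

## Refinement algorithm

Input: a network, a partition (typically from Louvain or CNM greedy
modularity — the engine only depends on the `detect` contract, so any
partitioner can be plugged in), and a configuration (γ, loss budget ρ,
detector for the incremental step, seed, round cap).

A work queue holds the refinable modules (`l_m > √(2L)`, with `L` always the
*original* network's global edge count — using subgraph edge counts would
change the threshold's meaning mid-recursion). Each round pops the module
with the most intra-module edges (largest-first: the biggest potential
losses are charged against the budget first, and the order is
deterministic), re-modularizes its induced subgraph with the detector, and
filters the sub-modules with the qualification test **evaluated in the
parent module's induced graph**, i.e. external degrees are counted with
respect to the sibling sub-modules. This locality is essential: in networks
whose mixing exceeds 0.5 (most molecular networks and all the benchmark
settings here), *every* node subset has more global external than internal
degree, so a globally-evaluated filter would reject everything and the
refinement would be a no-op. Failing sub-modules are regrouped into a single
remainder set. Accepted sub-modules and the remainder re-enter the queue if
they are themselves refinable.

Safeguards and conventions:

- A split that returns a single sub-module identical to its input marks the
  module non-refinable (prevents infinite loops on clique-like modules).
- A split in which no sub-module qualifies leaves the module untouched and
  frozen.
- **Loss budget.** The budget ρ meters the *accumulated losses* of accepted
  rounds: a round with ΔQ < 0 that would push the running loss total over ρ
  is reverted and its module frozen. Gains (possible when the initial
  partition is artificially sub-optimal, e.g. merged-block initializations)
  do not enlarge the budget — windfall profit must not fund the shattering
  of genuine modules. This accounting is strictly more conservative than
  net `Q_init − Q_final` accounting, so the invariant
  `Q_init − Q_final ≤ ρ` always holds. Default ρ = 0.2·|Q_init| — a
  relative default keeps the behaviour scale-free; set ρ = 0 to forbid any
  modularity-losing split (merged initializations are then un-merged
  exactly and nothing else changes).
- Convergence is reported as `no_refinable_left`, `loss_budget` (at least
  one round was reverted for exceeding the budget), or `max_rounds`.
- Determinism: one integer seed drives a per-round seed stream for the
  stochastic detector; identical configurations yield identical results.

Genealogy is tracked per final module as the chain of ancestor labels;
module node sets only shrink along a chain.

## Detectors

Louvain (`networkx.community.louvain_communities`, γ-aware, seeded), CNM
greedy modularity (`greedy_modularity_communities`, γ-aware, deterministic)
and asynchronous label propagation (`asyn_lpa_communities`, seeded, ignores
γ; ties are broken randomly under the seed, as the reference algorithm is
stochastic and no tie rule is canonical). On an edgeless network every
backend returns singletons.

## Evaluation protocol

- **NMI** between partitions: mutual information normalized by the
  arithmetic mean of the two label entropies (the symmetric, most common
  variant for non-overlapping partitions; computed via scikit-learn). A
  single-module partition has zero entropy and carries no information, so
  NMI is defined as 0 in that case.
- **Stability**: mean pairwise NMI over repeated seeded detection runs
  (default 25 in the sweep protocol).
- **Null model**: degree-preserving rewiring by double edge swaps
  (target 10·L successful swaps; self-loops and multi-edges are never
  created, so the degree sequence is preserved exactly on a simple graph).
  Rigid graphs such as a triangle are returned unchanged.
- **Significance**: z-score of the mean detected modularity against the
  null modularity distribution, plus the empirical p (fraction of null
  values at least as large). Zero null variance is reported as ±∞ with a
  warning.
- **Resolution selection**: among γ values whose empirical p is below 0.05
  (the conventional cutoff; no stricter value is canonical here), the most
  stable γ wins, ties broken toward more modules; if none is significant
  the most stable γ is returned with a warning flag.

## Synthetic benchmarks

`generate_lfr` produces LFR-style networks: power-law degrees (exponent 2,
average 20, maximum 0.1·N) and power-law community sizes (exponent 2,
minimum drawn per replicate from {30, 40, 50, 60, 70}, maximum 0.1·N),
with a per-node mixing parameter μ ∈ {0.55, 0.65, 0.75} — the fraction of
each node's edges that leave its planted community. These defaults mirror
the topology of large protein-interaction networks (heavy-tailed degrees,
heterogeneous module sizes, high interconnectedness).

The generator is implemented in-package because the widely available
implementation in networkx was measured to overshoot both the requested
average degree (≈28 realized for 20 requested) and the mixing (≈0.71
realized for μ = 0.55): its stub-completion step adds excess external
edges. The construction here splits each node's degree into an internal
part `(1−μ)d` and external part `μd`; internal degree sequences are
realized per community by Havel–Hakimi construction (after shaving
non-graphical surpluses onto the external side) followed by double-edge-
swap randomization, and the external stubs are paired by a configuration
model rewired until simple and free of intra-community edges. Measured
fidelity: mean degree within 3% of the target, realized mixing within 0.02
of μ, community sizes exactly within bounds. Node assignment to communities
is capacity-weighted so hubs do not pile into small communities.

What the generator does *not* emulate: degree–degree correlations beyond
the configuration model, clustering above the random expectation,
overlapping communities, and the incompleteness/noise structure of real
interactome data. Passing benchmarks therefore demonstrate correct
behaviour under the stated topological conditions, not performance on any
particular real interactome.

Planted-partition graphs (independent Bernoulli edges within/between
blocks) and rings of cliques (the classic resolution-limit construction)
serve as small deterministic oracles.

`run_lfr_experiment` runs the full grid — generate, detect, refine, score
both partitions against the planted truth — and returns tidy records
(two rows per replicate). Generator failures are logged and skipped, never
imputed. Runtime is recorded but hardware-dependent, so it is never
asserted on.

## Problem sizes in the shipped protocol

The acceptance script uses 10 replicates per mixing value at n = 5,000,
5 at n = 10,000 and 3 at n = 15,000 (54 benchmark networks in total), the
test suite a 10-replicate grid at n = 1,000 and n = 5,000. These sizes give
pooled NMI estimates stable to about one percentage point across seeds
while keeping a full run in the minutes range on a single core; the full
50-replicate grid is available through the `benchmark` command's options.

## Functional validation

Module enrichment is a one-sided hypergeometric over-representation test
per annotation term (scipy), with raw p-values thresholded at α = 0.05 by
default (the upstream convention; Benjamini–Hochberg adjustment is
available behind a flag). Per module the top ten significant terms are
kept, and the enriched fraction is the share of module genes annotated to
at least one of them. The partition-level summary averages this fraction
over meso-modules (more than 10 genes) — below that scale enrichment
fractions are not meaningful. The universe defaults to the annotated genes
present in the network.

Functional coverage of a gene-set collection: for each gene set, the
maximum Jaccard coefficient over all predicted modules; coverage is the
mean of these maxima. Gene sets are compared as given — genes absent from
the network are kept unless `restrict_to_network` is set, since dropping
them silently would inflate coverage.

`generate_synthetic_annotations` plants a designated term per module and
assigns it to each gene with probability `coherence` (else a uniformly
random term), giving a controllable, downloadable-data-free test bed for
the enrichment machinery.

## Known limitations

- The within-parent qualification filter can, with small probability,
  accept a favourable-fluctuation split of a genuinely homogeneous dense
  module; the loss budget bounds the damage (at most one such split under
  the default ρ in the planted-block setting measured). Setting ρ = 0
  eliminates it at the cost of forbidding all lossy refinement.
- Maximum refined module size tracks the largest *planted* community
  (up to 0.1·N in the benchmark settings): a correct refinement must not
  shatter a genuine large community, so no sub-200 size guarantee exists
  when larger true communities are present.
- Only simple undirected unweighted networks are supported; overlapping
  modules and convergence theory are out of scope.
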