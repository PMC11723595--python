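# Methods

## Model

A cancer's subclonal structure is modelled as a mutation tree: a rooted
arborescence whose root is the germline and whose `n` non-root nodes each
carry one somatic point mutation. The tree is equivalent to an `n × n`
binary genotype matrix `B` (`B[j, v] = 1` iff mutation `j` is `v` or an
ancestor of `v`), characterized by a unit diagonal, antisymmetric
ancestry, and laminar rows (each row is the clone set of a subtree, and
subtrees are pairwise nested or disjoint). Mixing the clones with
nonnegative proportions `U` (per-sample column sums ≤ 1; the remainder is
normal tissue) gives mutation frequencies `F = B U`. Reads follow a
binomial model, `b_js ~ Binom(N_js, ω_js F_js)`, with the variant read
probability `ω` supplied per locus and sample (½ for diploid CNA-free
loci). Samples are exchangeable; loci with `N = 0` contribute nothing.

Assumptions: the infinite sites assumption (each mutation acquired once,
never lost — no Dollo/loss events, no polytomy resolution), one mutation
per tree node, and CNA-affected loci either corrected through `ω` or
omitted by the user upstream.

## Search

The tree posterior is approximated by a product of per-mutation
conditionals along a fixed placement order π (descending mean observed
frequency, ties by total variant reads then input order — under the sum
rule an ancestor's frequency bounds its descendants' total, so ancestors
tend to be placed first). Each conditional scores all valid placements of
the next mutation — attach under any node `u` and adopt any subset of
`u`'s children — with a uniform prior `1/τ` over the `τ` placements times
the binomial likelihood of the placed mutations' data at the projected
point estimate `U*`.

Sampling without replacement uses Gumbel perturbations: placements get
`G_i = φ_i + Gumbel(0, 1)` noise and are conditioned on the parent's
perturbed score `T` through the truncated-Gumbel shift
`Ḡ_i = −log(exp(−T) − exp(−Z) + exp(−G_i))`, `Z = max_i G_i`, computed as
`−logaddexp(−T, log1p(−exp(G_i − Z)) − G_i)` so that `max_i Ḡ_i = T`
holds exactly in floating point. The beam keeps the `k` best partial
trees by `Ḡ`; when the popped tree is one mutation short of complete,
only the argmax extension is yielded and its complete siblings are
discarded (this mirrors the published pseudocode and surprises readers:
the yield count per final-level pop is one). The noise attached to a
node's extensions is a pure function of (seed, partial tree) — a
SeedSequence keyed by the parent vector — so runs with different beam
widths share one noise schedule, the global argmax leaf is found for any
`k ≥ 1`, and repeated runs with one seed are byte-identical. Chains
differ only in seeds derived deterministically from the master seed;
pooled trees are deduplicated on parent vectors and weighted by
softmax(φ).

The scores φ are unnormalized. The exact factorized construction would
normalize each conditional over all τ placements, but the branching
heuristic scores only `f` of them, so per-level normalization is
unavailable by design; the Gumbel machinery only requires scores up to a
per-sibling-set constant, which unnormalized log likelihoods provide.

### Branching heuristic

Before projection, placements are screened by a weighted frequency
sum-rule penalty: placing `v` under `u` adopting child set `S` costs, per
sample, `W_vs · [max(0, F̂_vs − avail_us)² + Σ_{c∈S} max(0, F̂_cs −
F̂_vs)²]` where `avail_us` is `u`'s frequency minus its non-adopted
children's (the root has frequency 1). The `f` cheapest survive, ties in
enumeration order. This is a stand-in with the intended contract (rank
placements by ISA adherence without running the projection); it is not a
bound on the likelihood.

## Projection

`U*` minimizes `‖W ⊙ (F̂ − B U)‖²` subject to `U ≥ 0`, per-sample sums
≤ 1, where `F̂ = clip(vaf/ω, 0, 1)` and `W` is the delta-method inverse
variance of `F̂` under binomial sampling, `W = ω² N / (λ̃(1 − λ̃))` with
the Jeffreys-smoothed VAF `λ̃ = (b + ½)/(N + 1)` keeping the weight
finite at VAFs of 0 or 1 (`W = 0` where `N = 0`). The problem separates
by sample into small convex QPs solved exactly: cyclic coordinate descent
on the nonnegativity cone, with the sum constraint enforced through its
scalar KKT multiplier found by bisection on the monotone map
μ → Σ u*(μ) (coordinate-descent tolerance 1e-14 on the largest
coordinate move; bisection to an interval of 1e-15). The solver is
numba-compiled and warm-started from the parent tree's `U` during search;
it matches a generic SLSQP solution to better than 1e-9 relative
objective on random instances. Likelihood evaluation clips `λ = ωF` into
`[1e-10, 1 − 1e-10]` before logs.

Using a point estimate `U*` instead of integrating over `U` is a
deliberate approximation; no marginalization or beta-binomial
overdispersion is attempted.

## Phylogeny-aware clustering

Given a tree and its fitted frequencies `F*` (tree-consistent by
default; the raw `F̂` is switchable), adjacent clone pairs are merged
agglomeratively by Ward's linkage `d(u,v) = n_u n_v/(n_u+n_v) ‖F̄_u −
F̄_v‖²` on size-weighted mean frequency rows. While any parent has a
single child, only such pairs may merge (re-checked every iteration,
since merges can recreate them); otherwise any parent–child edge is
eligible, plus pairs of root children — without the latter a star-shaped
level has no edges and could never contract to one clone, and two root
children are adjacent through the (unmergeable) germline root. Ties
break on the smallest label pair. The resulting path of `n` nested
clusterings (sizes n..1) is scored by the pooled binomial likelihood
(clone VAF `λ_is = Σ b / Σ N`, the maximizer of the clustering
likelihood for fixed assignments) and the clone count is chosen by
`GIC = −2L + log(nm) · (cm)` — a BIC-like member of the GIC family with
`c·m` free clone-VAF parameters — with ties going to fewer clones. The
full GIC curve is reported for auditability. Both the penalty and the
λ estimator are explicit configuration points of the implementation.

## Synthetic data

The generator emulates multi-region bulk sequencing of a CNA-free
diploid cancer: a uniform-attachment random tree (node `j` picks its
parent uniformly from the root and nodes `1..j−1`, which respects the
ISA by construction), per-sample clonal proportions
`(U_1..U_n, U_normal) ~ Dirichlet(α·1)` with `α = 1` by default, exact
frequencies `F = B U`, Poisson(depth) total reads truncated to ≥ 1, and
binomial variant reads at `λ = ωF` with `ω = ½` everywhere. Defaults are
depth 200x with 10 samples, the smallest tier of a realistic multi-region
design. Planted-clone simulations draw a clone tree, assign every clone
at least one mutation, and expand clones into chains so mutations within
a clone share an identical frequency row.

What the generator does not emulate: sequencing error and strand biases,
copy-number aberrations (ω is constant), overdispersion beyond binomial
sampling, sample contamination, and correlated depths across loci.
Passing the recovery tests therefore demonstrates correctness of the
inference machinery under the generative model, not robustness to real
data artifacts.

## Metrics

Log perplexity ratio: per-entry binomial log-likelihood gap in bits,
`(1/nm) Σ [log2 P(b | N, ωF_baseline) − log2 P(b | N, ωF)]`, averaged
over distinct trees with posterior weights; negative means a better fit
than the baseline (the generating `F` for simulations). Note that a
fitted `F*` has nearly one free parameter per entry, so against the
generating frequencies this metric sits well below zero at any depth
(likelihood-ratio asymptotics give ≈ 0.72 bits/entry of overfit headroom);
it is a comparative score, not a consistency diagnostic.

Relationship reconstruction loss: for every unordered mutation pair, the
distribution over {ancestral, descendant, branched, cocluster} implied by
the weighted tree set is compared with the ground-truth set's by
Jensen-Shannon divergence (base 2, 0·log 0 = 0); the loss is the mean
over pairs, ranging from 0 (complete match) to 1 bit (complete
mismatch). Cocluster has structurally zero mass for mutation trees and is
kept for forward compatibility with clone trees.

## Numerical and design choices

- Trees are parent maps keyed by mutation label with the root as a
  sentinel; extension application is O(1) and parent vectors are the
  canonical deduplication key. Genotype matrices are materialized only
  for scoring and export.
- Extension enumeration order is deterministic (node ascending, child
  subsets in bitmask order), so a seed fully determines a run.
- Gumbel draws use −log(−log U) with U bounded away from 0.
- Duplicate trees across chains are collapsed before weighting (the
  factorized sampler guarantees distinctness only within a chain).
- Degenerate inputs: `N = 0` entries are flagged unobserved and carry
  zero weight and zero likelihood; `ω = 0` with `b > 0` is rejected as
  impossible; frequency estimates are clipped to [0, 1].

## Problem sizes

The test suite and the acceptance script use 20 replicates of
10 mutations × 10 samples at 200x (beam width 10, branching factor 20)
for end-to-end recovery, 5 mutations at 10⁶x for the noise-free exact
recovery check, n ≤ 4 for exhaustive tree-space oracles, and 20 planted
5-clone cancers (20 mutations × 10 samples at 200x) for clustering
recovery; these sizes exercise every code path while keeping a full run
in the minutes range on one CPU.

## Known limitations

- The heuristic, weight matrix, placement order, and GIC penalty are
  documented stand-ins with the published contracts; the original
  supplementary formulations may differ in detail.
- Beam search yields at most one complete tree per popped final-level
  parent, so fewer than `k` trees can be returned on very small trees
  (e.g. exactly one tree for n = 2 regardless of k).
- No copy-number tree inference, no VCF parsing, no MCMC or MILP modes,
  and no probabilistic merge criterion in the clustering.
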