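"""Synthetic bulk-VAF data generation and reconstruction metrics.

The generator draws a random mutation tree (uniform attachment, which
respects the infinite sites assumption by construction), Dirichlet clonal
proportions per sample with a reserved normal-cell fraction, exact
tree-implied frequencies F = B U, and binomial read counts at a Poisson
sequencing depth.  Defaults (depth 200x, omega 1/2 everywhere, Dirichlet
concentration 1) emulate multi-region WGS of a CNA-free diploid cancer.

Two metrics compare reconstructions against a baseline: the log
perplexity ratio (per-entry binomial log-likelihood gap, in bits;
negative = better fit than baseline) and the relationship reconstruction
loss (mean Jensen-Shannon divergence, in bits, between the distributions
of pairwise evolutionary relations implied by the reconstructed and true
tree sets).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.distance import jensenshannon

from .io_formats import ResultArchive, VafDataset
from .likelihood import binom_logpmf
from .phylo_model import (
    ROOT,
    MutationTree,
    N_RELATIONS,
    pairwise_relations,
    tree_to_genotype,
)

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_tree",
    "simulate_proportions",
    "simulate_reads",
    "simulate",
    "simulate_clustered",
    "log_perplexity_ratio",
    "relationship_loss",
]

LOG2 = np.log(2.0)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic cancer.

    depth is the mean reads per locus (Poisson); dirichlet_alpha the
    concentration of the per-sample clonal proportions (1 = uniform over
    the simplex); omega the variant read probability everywhere (1/2 for
    diploid CNA-free loci).
    """

    n_mutations: int
    n_samples: int
    depth: float = 200.0
    dirichlet_alpha: float = 1.0
    omega: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_mutations < 1 or self.n_samples < 1 or self.depth < 1:
            raise ValueError("need n >= 1 mutations, m >= 1 samples, depth >= 1")


@dataclass
class GroundTruth:
    """A simulated cancer: the planted tree/matrices and the VAF dataset."""

    tree: MutationTree
    B: np.ndarray
    U: np.ndarray
    F: np.ndarray            # = B @ U exactly
    data: VafDataset
    clone_assignment: np.ndarray | None = None  # planted clones, if clustered


def simulate_tree(n: int, rng: np.random.Generator) -> MutationTree:
    """Random recursive tree: node j attaches uniformly to {root, 1..j-1}."""
    if n < 1:
        raise ValueError("need at least one mutation")
    parent = {1: ROOT}
    for j in range(2, n + 1):
        parent[j] = int(rng.integers(0, j))  # 0 = root
    return MutationTree(parent)


def simulate_proportions(
    tree: MutationTree, m: int, alpha: float, rng: np.random.Generator
) -> np.ndarray:
    """Per-sample clonal proportions: (U_1..U_n, U_normal) ~ Dirichlet(alpha).

    Returns the n x m matrix U; the dropped last component is the normal
    fraction, so column sums are <= 1.
    """
    n = tree.node_count
    draws = rng.dirichlet(np.full(n + 1, float(alpha)), size=m)  # m x (n+1)
    return draws[:, :n].T.copy()


def simulate_reads(
    F: np.ndarray, depth: float, omega: np.ndarray | float, rng: np.random.Generator
) -> VafDataset:
    """Binomial read counts: N ~ Poisson(depth) (>= 1), b ~ Binom(N, omega F)."""
    F = np.asarray(F, dtype=np.float64)
    n, m = F.shape
    omega = np.broadcast_to(np.asarray(omega, dtype=np.float64), F.shape).copy()
    N = np.maximum(rng.poisson(depth, size=F.shape), 1)
    b = rng.binomial(N, np.clip(omega * F, 0.0, 1.0))
    return VafDataset(
        mutation_ids=[f"s{j}" for j in range(n)],
        mutation_names=[f"S_{j}" for j in range(n)],
        var_reads=b,
        ref_reads=N - b,
        omega=omega,
        sample_names=[f"Sample {s+1}" for s in range(m)],
    )


def simulate(config: SimulationConfig) -> GroundTruth:
    """Generate one complete synthetic cancer under ``config``."""
    rng = np.random.default_rng(config.seed)
    tree = simulate_tree(config.n_mutations, rng)
    B = tree_to_genotype(tree, order=range(1, config.n_mutations + 1)).astype(np.float64)
    U = simulate_proportions(tree, config.n_samples, config.dirichlet_alpha, rng)
    F = B @ U
    data = simulate_reads(F, config.depth, config.omega, rng)
    return GroundTruth(tree=tree, B=B, U=U, F=F, data=data)


def simulate_clustered(
    n: int,
    n_clones: int,
    m: int,
    depth: float = 200.0,
    dirichlet_alpha: float = 1.0,
    omega: float = 0.5,
    seed: int = 0,
) -> GroundTruth:
    """Planted-clone simulation: a clone tree over ``n_clones`` clones, each
    expanded into a chain of its member mutations, so mutations within one
    clone share the exact same frequency row.

    Every clone receives at least one mutation; the remainder are assigned
    uniformly at random.  The returned tree is the expanded mutation tree
    and ``clone_assignment`` the planted labels.
    """
    if not 1 <= n_clones <= n:
        raise ValueError("need 1 <= n_clones <= n")
    rng = np.random.default_rng(seed)
    ctree = simulate_tree(n_clones, rng)
    U_clone = simulate_proportions(ctree, m, dirichlet_alpha, rng)  # c x m
    B_clone = tree_to_genotype(ctree, order=range(1, n_clones + 1)).astype(np.float64)
    F_clone = B_clone @ U_clone

    assignment = np.concatenate([
        np.arange(n_clones), rng.integers(0, n_clones, size=n - n_clones)
    ])
    rng.shuffle(assignment)

    # Expand each clone into a chain of its mutations; a clone-tree edge
    # becomes an edge from the last mutation of the parent chain to the
    # first of the child chain.
    chains = {c: [int(j) + 1 for j in np.flatnonzero(assignment == c)] for c in range(n_clones)}
    parent: dict[int, int] = {}
    for c in range(n_clones):
        chain = chains[c]
        pc = ctree.parent_of(c + 1)
        head_parent = ROOT if pc == ROOT else chains[pc - 1][-1]
        parent[chain[0]] = head_parent
        for prev, nxt in zip(chain, chain[1:]):
            parent[nxt] = prev
    tree = MutationTree(parent)

    F = F_clone[assignment]  # n x m, identical rows within a clone
    # mutation-level U: the clone's proportion mass sits on the clone's
    # terminal mutation; interior chain nodes get 0
    U = np.zeros((n, m))
    for c in range(n_clones):
        U[chains[c][-1] - 1] = U_clone[c]
    B = tree_to_genotype(tree, order=range(1, n + 1)).astype(np.float64)
    data = simulate_reads(F, depth, omega, rng)
    return GroundTruth(tree=tree, B=B, U=U, F=F, data=data, clone_assignment=assignment)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


def log_perplexity_ratio(
    archive: ResultArchive, baseline_F: np.ndarray, data: VafDataset
) -> float:
    """Weight-averaged log perplexity ratio, in bits.

    For one tree with fitted frequencies F,
    LPR = (1/(n m)) sum_{j,s} [log2 Binom(b | N, omega F_baseline)
                               - log2 Binom(b | N, omega F)],
    averaged with the archive's posterior weights.  Negative means the
    reconstruction fits the reads better than the baseline.
    """
    baseline_F = np.asarray(baseline_F, dtype=np.float64)
    b, N, omega = data.var_reads, data.total_reads, data.omega
    if baseline_F.shape != b.shape:
        raise ValueError("baseline frequency matrix shape mismatch")
    base_ll = binom_logpmf(b, N, omega * baseline_F) / LOG2
    nm = b.size
    out = 0.0
    for t in range(archive.n_trees):
        tree_ll = binom_logpmf(b, N, omega * archive.F[t]) / LOG2
        out += archive.weights[t] * float((base_ll - tree_ll).sum()) / nm
    return out


def _relation_distributions(
    trees: Sequence[MutationTree], weights: np.ndarray | None, n: int
) -> np.ndarray:
    """Weighted distribution over the four relation categories for each
    unordered mutation pair; shape (n_pairs, 4)."""
    if weights is None:
        weights = np.full(len(trees), 1.0 / len(trees))
    weights = np.asarray(weights, dtype=np.float64)
    iu, ju = np.triu_indices(n, k=1)
    dist = np.zeros((iu.size, N_RELATIONS))
    for w, tree in zip(weights, trees):
        rel = pairwise_relations(tree, n)
        codes = rel[iu, ju]
        dist[np.arange(iu.size), codes] += w
    return dist


def _as_trees_weights(x) -> tuple[list[MutationTree], np.ndarray | None]:
    if isinstance(x, ResultArchive):
        return x.trees(), x.weights
    return list(x), None


def relationship_loss(archive, truth_trees) -> float:
    """Mean pairwise Jensen-Shannon divergence (base 2) between relation
    distributions of a reconstruction and of the ground-truth tree set.

    Both arguments may be a :class:`ResultArchive` (posterior-weighted) or
    a plain sequence of trees (uniform weights).  The loss lies in [0, 1]
    bits: 0 for a complete match of pairwise relationships, 1 for a
    complete mismatch.
    """
    trees_a, w_a = _as_trees_weights(archive)
    trees_b, w_b = _as_trees_weights(truth_trees)
    n = trees_a[0].node_count
    if any(t.node_count != n for t in trees_a + trees_b):
        raise ValueError("all trees must cover the same mutation set")
    if n < 2:
        return 0.0
    P = _relation_distributions(trees_a, w_a, n)
    Q = _relation_distributions(trees_b, w_b, n)
    jsd = jensenshannon(P.T, Q.T, base=2.0) ** 2
    jsd = np.nan_to_num(jsd, nan=0.0)  # identical zero-support pairs
    return float(jsd.mean())
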