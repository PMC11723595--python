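"""Stochastic beam search over partial mutation trees.

The search maintains a queue of at most k partial trees ranked by their
shifted perturbed log scores.  At each step the best entry is popped and
extended with the next mutation in the placement order pi; extensions are
pre-screened by a cheap sum-rule (ISA) adherence heuristic, the survivors
are scored by the projection-based likelihood and perturbed with Gumbel
noise conditioned on the parent's score, and the queue is truncated back
to k.  Because the noise attached to a node is a pure function of the
node's identity, the search returns exactly the top-k complete trees of
one joint perturbation of the search tree's leaves — i.e. k samples
without replacement from the factorized posterior approximation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .io_formats import ResultArchive, VafDataset
from .likelihood import (
    compute_weights,
    data_log_likelihood,
    estimate_frequencies,
    fit_clonal_proportions,
)
from .phylo_model import (
    ROOT,
    MutationTree,
    TreeExtension,
    apply_extension,
    enumerate_extensions,
    tree_to_genotype,
)
from .sampler import node_generator, sample_gumbel, shift_perturbed

__all__ = [
    "SearchConfig",
    "ScoredTree",
    "choose_order",
    "heuristic_filter",
    "beam_search",
    "run_chains",
]


@dataclass(frozen=True)
class SearchConfig:
    """Knobs of the stochastic beam search.

    beam_width
        k, the number of partial trees retained per iteration (and the
        number of complete trees sampled without replacement).
    branching_factor
        f, the number of heuristic-filtered extensions scored per pop;
        ``None`` means no filtering (score every valid placement).
    order
        Mutation placement order pi (labels 1..n); derived from the data
        when omitted.
    """

    beam_width: int = 10
    branching_factor: int | None = 20
    order: tuple[int, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.beam_width < 1:
            raise ValueError("beam width must be >= 1")
        if self.branching_factor is not None and self.branching_factor < 1:
            raise ValueError("branching factor must be >= 1")


@dataclass
class ScoredTree:
    """A complete tree yielded by the search with its scores and fit."""

    tree: MutationTree
    log_score: float          # phi, projection-based
    gumbel: float             # G_phi = phi + Gumbel noise
    shifted: float            # Gbar_phi, conditioned perturbed score
    U: np.ndarray             # clonal proportions, rows in input order
    F: np.ndarray             # tree-implied frequencies, rows in input order


@dataclass
class _BeamEntry:
    tree: MutationTree
    shifted: float
    gumbel: float
    phi: float
    prior: float              # accumulated -log(tau) terms
    U: np.ndarray             # rows in pi-prefix order (warm start)


def choose_order(data: VafDataset) -> tuple[int, ...]:
    """Placement order pi: mutations by descending mean observed frequency.

    Under the sum rule an ancestor's frequency bounds its descendants'
    total, so high-frequency mutations are placed first.  Ties break by
    descending total variant reads, then input order (stable).
    """
    F_hat = estimate_frequencies(data)
    mean_f = F_hat.mean(axis=1)
    tot_var = data.var_reads.sum(axis=1)
    idx = np.lexsort((np.arange(data.n_mutations), -tot_var, -mean_f))
    return tuple(int(i) + 1 for i in idx)


def heuristic_filter(
    tree: MutationTree,
    new_mutation: int,
    data: VafDataset,
    f: int | None,
    F_hat: np.ndarray | None = None,
    W: np.ndarray | None = None,
    extensions: Sequence[TreeExtension] | None = None,
) -> list[TreeExtension]:
    """Keep the f extensions that best respect the frequency sum rule.

    Placing mutation v under u while adopting child set S is penalized,
    per sample, by the weighted squared amounts by which (i) v's observed
    frequency exceeds the headroom left at u by the non-adopted children
    and (ii) each adopted child's frequency exceeds v's:

        penalty = sum_s W_vs * [ max(0, F_vs - avail_us)^2
                                 + sum_{c in S} max(0, F_cs - F_vs)^2 ],

    with avail_us = F_us - sum_{c in children(u) \\ S} F_cs (the root has
    F_rs = 1).  The penalty is computed without running the projection;
    ties keep enumeration order (stable sort).
    """
    if f is not None and f < 1:
        raise ValueError("branching factor must be >= 1")
    if extensions is None:
        extensions = enumerate_extensions(tree, new_mutation)
    if f is None or f >= len(extensions):
        return list(extensions)
    if F_hat is None:
        F_hat = estimate_frequencies(data)
    if W is None:
        W = compute_weights(data)

    fv = F_hat[new_mutation - 1]
    wv = W[new_mutation - 1]
    penalties = np.empty(len(extensions))
    for i, ext in enumerate(extensions):
        u = ext.attach_node
        fu = np.ones(data.n_samples) if u == ROOT else F_hat[u - 1]
        avail = fu.copy()
        for c in tree.children_of(u):
            if c not in ext.adopted_children:
                avail -= F_hat[c - 1]
        pen = np.maximum(0.0, fv - avail) ** 2
        for c in ext.adopted_children:
            pen += np.maximum(0.0, F_hat[c - 1] - fv) ** 2
        penalties[i] = float((wv * pen).sum())
    keep = np.argsort(penalties, kind="stable")[:f]
    keep.sort()  # preserve enumeration order among the survivors
    return [extensions[i] for i in keep]


def _score_extension(
    entry: _BeamEntry,
    ext: TreeExtension,
    tau: int,
    data: VafDataset,
    F_hat: np.ndarray,
    W: np.ndarray,
    prefix: Sequence[int],
) -> tuple[MutationTree, float, float, np.ndarray]:
    """Score one extension: new tree, phi, prior and fitted U (pi order)."""
    new_tree = apply_extension(entry.tree, ext)
    labels = list(prefix)
    rows = [lab - 1 for lab in labels]
    B = tree_to_genotype(new_tree, order=labels).astype(np.float64)
    warm = np.vstack([entry.U, np.zeros((1, entry.U.shape[1]))])
    U, _ = fit_clonal_proportions(B, F_hat[rows], W[rows], warm_start=warm)
    prior = entry.prior - math.log(tau)
    phi = prior + data_log_likelihood(data, B, U, rows=rows)
    return new_tree, phi, prior, U


def beam_search(data: VafDataset, config: SearchConfig) -> list[ScoredTree]:
    """Sample up to k complete trees without replacement.

    The first tree holds only pi_1 and starts with shifted and raw
    perturbed scores of 0.  Each iteration pops the entry with the largest
    shifted score, perturbs the scores of its (filtered) extensions, and
    either yields the best complete extension (decrementing k) or shifts
    the extensions' scores against the parent's and pushes them back,
    truncating the queue to k.  At least one tree is always returned;
    results are sorted by phi descending.
    """
    n = data.n_mutations
    pi = config.order if config.order is not None else choose_order(data)
    pi = tuple(pi)
    if sorted(pi) != list(range(1, n + 1)):
        raise ValueError("order must be a permutation of 1..n")
    F_hat = estimate_frequencies(data)
    W = compute_weights(data)
    m = data.n_samples

    first = MutationTree({pi[0]: ROOT})
    B1 = np.ones((1, 1))
    U1, _ = fit_clonal_proportions(B1, F_hat[[pi[0] - 1]], W[[pi[0] - 1]])
    phi1 = data_log_likelihood(data, B1, U1, rows=[pi[0] - 1])
    queue = [_BeamEntry(first, 0.0, 0.0, phi1, 0.0, U1)]
    k = config.beam_width
    results: list[ScoredTree] = []

    while queue and k > 0:
        queue.sort(key=lambda e: -e.shifted)
        entry = queue.pop(0)
        ell = entry.tree.node_count
        if ell == n:  # only possible when n == 1
            results.append(_finalize(entry, pi, m, n))
            k -= 1
            continue
        new_label = pi[ell]
        exts = enumerate_extensions(entry.tree, new_label)
        tau = len(exts)
        cands = heuristic_filter(
            entry.tree, new_label, data, config.branching_factor,
            F_hat=F_hat, W=W, extensions=exts,
        )
        prefix = pi[: ell + 1]
        scored = [
            _score_extension(entry, ext, tau, data, F_hat, W, prefix)
            for ext in cands
        ]
        phis = np.array([s[1] for s in scored])
        rng = node_generator(config.seed, entry.tree)
        G = phis + sample_gumbel(len(cands), rng)
        if ell + 1 == n:
            i_best = int(np.argmax(G))
            tree_b, phi_b, _, U_b = scored[i_best]
            Gbar = shift_perturbed(entry.shifted, G)
            results.append(
                ScoredTree(tree_b, phi_b, float(G[i_best]), float(Gbar[i_best]),
                           *_reorder(U_b, pi, m, n))
            )
            k -= 1
            continue
        Gbar = shift_perturbed(entry.shifted, G)
        for i, (tree_i, phi_i, prior_i, U_i) in enumerate(scored):
            queue.append(_BeamEntry(tree_i, float(Gbar[i]), float(G[i]), phi_i, prior_i, U_i))
        queue.sort(key=lambda e: -e.shifted)
        del queue[k:]

    results.sort(key=lambda s: -s.log_score)
    _fill_F(results, n)
    return results


def _reorder(U: np.ndarray, pi: Sequence[int], m: int, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Permute a pi-ordered U back to input mutation order; return (U, F)."""
    U_full = np.zeros((n, m))
    for i, lab in enumerate(pi[: U.shape[0]]):
        U_full[lab - 1] = U[i]
    return U_full, None  # F filled by caller once the tree is known


def _finalize(entry: _BeamEntry, pi, m, n) -> ScoredTree:
    U_full, _ = _reorder(entry.U, pi, m, n)
    return ScoredTree(entry.tree, entry.phi, entry.gumbel, entry.shifted, U_full, None)


def _fill_F(results: list[ScoredTree], n: int) -> None:
    for st in results:
        B = tree_to_genotype(st.tree, order=range(1, n + 1)).astype(np.float64)
        st.F = B @ st.U


def run_chains(data: VafDataset, config: SearchConfig, n_chains: int = 1) -> ResultArchive:
    """Run independent chains, pool and deduplicate, weight by likelihood.

    Chains differ only in deterministically derived seeds.  Trees are
    deduplicated on parent vectors; posterior weights over distinct trees
    are softmax(phi).
    """
    if n_chains < 1:
        raise ValueError("need at least one chain")
    n, m = data.n_mutations, data.n_samples
    pooled: dict[tuple[int, ...], ScoredTree] = {}
    for chain in range(n_chains):
        chain_seed = int(np.random.SeedSequence([config.seed, chain]).generate_state(1)[0])
        chain_seed &= 0x7FFFFFFF
        res = beam_search(data, replace(config, seed=chain_seed))
        for st in res:
            key = tuple(int(x) for x in st.tree.parent_vector(n))
            if key not in pooled or st.log_score > pooled[key].log_score:
                pooled[key] = st
    trees = sorted(pooled.values(), key=lambda s: -s.log_score)
    phis = np.array([t.log_score for t in trees])
    w = np.exp(phis - phis.max())
    w /= w.sum()
    return ResultArchive(
        parents=np.array([t.tree.parent_vector(n) for t in trees]),
        log_scores=phis,
        weights=w,
        U=np.array([t.U for t in trees]),
        F=np.array([t.F for t in trees]),
        metadata={
            "beam_width": config.beam_width,
            "branching_factor": config.branching_factor,
            "order": list(config.order) if config.order is not None else None,
            "seed": config.seed,
            "n_chains": n_chains,
        },
    )
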