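"""Phylogeny-aware agglomerative clustering of mutations into clones.

Instead of clustering VAFs in isolation, the clustering walks a
reconstructed mutation tree and repeatedly contracts the adjacent
(parent-child) pair with the smallest Ward distance between the nodes'
mean frequency profiles.  While any node has a single child, only such
parent/only-child pairs may merge; once none remain, any adjacent pair is
eligible (re-checked at every step, since merges can recreate only-child
pairs).  This yields a nested path of n clusterings with 1..n clones,
each of which stays connected in the source tree; the clustering that
minimizes a Generalized Information Criterion is selected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .io_formats import VafDataset
from .likelihood import binom_logpmf, compute_weights, estimate_frequencies, fit_clonal_proportions
from .phylo_model import ROOT, MutationTree, tree_to_genotype

__all__ = [
    "CloneTree",
    "ClusterState",
    "ClusteringPath",
    "ward_distance",
    "agglomerate",
    "pooled_clone_vafs",
    "clustering_log_likelihood",
    "gic_select",
    "infer_clone_tree",
]


@dataclass
class ClusterState:
    """One clustering on the agglomeration path.

    ``members[i]`` is the set of mutation labels in clone ``i``;
    ``parent[i]`` is the clone's parent clone index (-1 = root);
    ``means[i]`` is the size-weighted mean frequency profile.
    """

    members: list[frozenset[int]]
    parent: list[int]
    means: np.ndarray  # (c, m)

    @property
    def n_clones(self) -> int:
        return len(self.members)

    def assignment(self, n: int) -> np.ndarray:
        """Clone index per mutation label 1..n."""
        out = np.empty(n, dtype=np.int64)
        for i, mem in enumerate(self.members):
            for j in mem:
                out[j - 1] = i
        return out

    def Z(self, n: int) -> np.ndarray:
        """n x c binary assignment matrix (rows sum to 1)."""
        Z = np.zeros((n, self.n_clones), dtype=np.int8)
        Z[np.arange(n), self.assignment(n)] = 1
        return Z


@dataclass
class ClusteringPath:
    """The n nested clusterings (sizes n..1) with optional scores."""

    states: list[ClusterState]
    n_mutations: int
    log_likelihoods: list[float] = field(default_factory=list)
    gic: list[float] = field(default_factory=list)


@dataclass
class CloneTree:
    """Selected clone tree: assignments, clone VAFs, and the GIC audit trail."""

    parent: list[int]          # parent clone index per clone, -1 = root
    Z: np.ndarray              # n x c binary assignment
    assignment: np.ndarray     # clone index per mutation
    clone_vafs: np.ndarray     # c x m pooled VAF estimates (lambda)
    gic_table: list[tuple[int, float, float]]  # (c, log-likelihood, GIC)

    @property
    def n_clones(self) -> int:
        return len(self.parent)


def ward_distance(
    u: int,
    v: int,
    sizes,
    means,
    parent: dict[int, int] | None = None,
) -> float:
    """Ward's linkage d(u, v) = n_u n_v / (n_u + n_v) * ||mean_u - mean_v||^2.

    ``sizes`` and ``means`` map node ids to mutation counts and mean
    frequency profiles.  If ``parent`` (a parent map) is given, the pair
    must be adjacent: parent/child in either direction, or two children of
    the germline root (which are connected through it — the root itself
    can never be merged).
    """
    if parent is not None:
        adjacent = (
            parent.get(u) == v
            or parent.get(v) == u
            or (parent.get(u) == ROOT and parent.get(v) == ROOT)
        )
        if not adjacent:
            raise ValueError(f"nodes {u} and {v} are not adjacent")
    nu, nv = sizes[u], sizes[v]
    diff = np.asarray(means[u], float) - np.asarray(means[v], float)
    return float(nu * nv / (nu + nv) * np.dot(diff, diff))


def agglomerate(tree: MutationTree, F: np.ndarray) -> ClusteringPath:
    """Contract ``tree`` edge by edge into the full clustering path.

    ``F`` holds one frequency row per mutation (input order).  Merging a
    child into its parent unions the member sets, size-weights the means,
    and reattaches the child's children to the merged node, so every clone
    is a connected node set of the source tree.  Ties in the Ward distance
    break on the smallest (parent, child) label pair.
    """
    n = tree.node_count
    if set(tree.labels) != set(range(1, n + 1)):
        raise ValueError("agglomerate requires a complete tree over 1..n")
    F = np.asarray(F, dtype=np.float64)

    members = {v: frozenset([v]) for v in tree.labels}
    parent = {v: tree.parent_of(v) for v in tree.labels}
    sizes = {v: 1 for v in tree.labels}
    means = {v: F[v - 1].copy() for v in tree.labels}

    def snapshot() -> ClusterState:
        order = sorted(members)
        index = {v: i for i, v in enumerate(order)}
        par = [index[parent[v]] if parent[v] != ROOT else -1 for v in order]
        return ClusterState(
            members=[members[v] for v in order],
            parent=par,
            means=np.array([means[v] for v in order]),
        )

    states = [snapshot()]
    while len(members) > 1:
        edges = [(p, c) for c, p in parent.items() if p != ROOT]
        child_count: dict[int, int] = {}
        for p, _ in edges:
            child_count[p] = child_count.get(p, 0) + 1
        only_child = [(p, c) for p, c in edges if child_count[p] == 1]
        if only_child:
            candidates = only_child
        else:
            # root children are mutually adjacent through the (unmergeable)
            # root, so star-shaped levels can still contract to one clone
            roots = sorted(v for v, pv in parent.items() if pv == ROOT)
            root_pairs = [(roots[i], roots[j])
                          for i in range(len(roots)) for j in range(i + 1, len(roots))]
            candidates = edges + root_pairs
        a_best, b_best = min(
            candidates,
            key=lambda pc: (ward_distance(pc[0], pc[1], sizes, means, parent), pc),
        )
        # absorb b into a; for an edge, a is the parent, so contraction
        # preserves the arborescence
        w_a = sizes[a_best] / (sizes[a_best] + sizes[b_best])
        means[a_best] = w_a * means[a_best] + (1 - w_a) * means[b_best]
        sizes[a_best] += sizes[b_best]
        members[a_best] = members[a_best] | members[b_best]
        for v, pv in list(parent.items()):
            if pv == b_best:
                parent[v] = a_best
        del members[b_best], parent[b_best], sizes[b_best], means[b_best]
        states.append(snapshot())

    return ClusteringPath(states=states, n_mutations=n)


def pooled_clone_vafs(data: VafDataset, members: list[frozenset[int]]) -> np.ndarray:
    """Per-clone, per-sample pooled binomial MLE of the clone VAF:
    lambda_is = sum_{j in clone i} b_js / sum_{j in clone i} N_js."""
    N = data.total_reads
    lam = np.zeros((len(members), data.n_samples))
    for i, mem in enumerate(members):
        if not mem:
            raise ValueError("empty clone")
        rows = [j - 1 for j in sorted(mem)]
        num = data.var_reads[rows].sum(axis=0)
        den = N[rows].sum(axis=0)
        lam[i] = np.where(den > 0, num / np.maximum(den, 1), 0.0)
    return lam


def clustering_log_likelihood(data: VafDataset, Z: np.ndarray, lam: np.ndarray) -> float:
    """Binomial clustering likelihood: each mutation's per-sample counts are
    scored against its clone's VAF lambda_is."""
    Z = np.asarray(Z)
    if (Z.sum(axis=0) == 0).any():
        raise ValueError("empty clone")
    if (Z.sum(axis=1) != 1).any():
        raise ValueError("each mutation must belong to exactly one clone")
    assign = Z.argmax(axis=1)
    lam_per_mut = np.asarray(lam, dtype=np.float64)[assign]  # n x m
    return float(binom_logpmf(data.var_reads, data.total_reads, lam_per_mut).sum())


def gic_select(path: ClusteringPath, data: VafDataset) -> int:
    """Score every clustering on the path and return the index minimizing

        GIC = -2 L + log(n m) * (c m),

    i.e. a BIC-like information criterion with c*m free clone-VAF
    parameters.  Ties go to fewer clones.  Fills ``path.log_likelihoods``
    and ``path.gic`` for auditability.
    """
    n, m = path.n_mutations, data.n_samples
    penalty_rate = math.log(n * m)
    path.log_likelihoods = []
    path.gic = []
    for state in path.states:
        lam = pooled_clone_vafs(data, state.members)
        L = clustering_log_likelihood(data, state.Z(n), lam)
        path.log_likelihoods.append(L)
        path.gic.append(-2.0 * L + penalty_rate * state.n_clones * m)
    # ties -> fewer clones: states run from n clones down to 1, so scan in
    # increasing-c order and keep strict improvement
    best = len(path.states) - 1
    for i in range(len(path.states) - 2, -1, -1):
        if path.gic[i] < path.gic[best]:
            best = i
    return best


def infer_clone_tree(
    tree: MutationTree,
    data: VafDataset,
    use_fitted_frequencies: bool = True,
) -> CloneTree:
    """Full pipeline: project frequencies onto the tree, agglomerate, and
    pick the GIC-optimal clone tree.

    With ``use_fitted_frequencies`` the Ward means use the tree-consistent
    F* from the projection (default); otherwise the raw observed
    frequencies.
    """
    n = tree.node_count
    F_hat = estimate_frequencies(data)
    if use_fitted_frequencies:
        order = list(range(1, n + 1))
        B = tree_to_genotype(tree, order=order).astype(np.float64)
        _, F = fit_clonal_proportions(B, F_hat, compute_weights(data))
    else:
        F = F_hat
    path = agglomerate(tree, F)
    best = gic_select(path, data)
    state = path.states[best]
    lam = pooled_clone_vafs(data, state.members)
    gic_table = [
        (st.n_clones, path.log_likelihoods[i], path.gic[i])
        for i, st in enumerate(path.states)
    ]
    return CloneTree(
        parent=state.parent,
        Z=state.Z(n),
        assignment=state.assignment(n),
        clone_vafs=lam,
        gic_table=gic_table,
    )
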