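"""Mutation trees, binary genotype matrices, and their interconversion.

A *mutation tree* is a rooted arborescence in which every non-root node
carries exactly one somatic mutation; the subtree below a node is the
subclone founded by that mutation.  Under the infinite sites assumption
(each mutation acquired once, never lost) a mutation tree is equivalent
to a perfect-phylogeny-compatible binary genotype matrix ``B`` in which
``B[j, v] == 1`` iff clone ``v`` carries mutation ``j`` (i.e. ``j`` is
``v`` itself or one of its ancestors).

Mutations are labelled by positive integers; the germline root is the
sentinel :data:`ROOT` (0).  Trees are stored as parent maps keyed by
mutation label, which makes extension application O(1) and gives cheap,
canonical hashing for deduplication.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

ROOT = 0

__all__ = [
    "ROOT",
    "MutationTree",
    "TreeExtension",
    "ANCESTRAL",
    "DESCENDANT",
    "BRANCHED",
    "COCLUSTER",
    "tree_to_genotype",
    "genotype_to_tree",
    "is_perfect_phylogeny",
    "enumerate_extensions",
    "count_extensions",
    "apply_extension",
    "pairwise_relations",
]


class MutationTree:
    """Rooted arborescence over :data:`ROOT` plus labelled mutation nodes.

    Parameters
    ----------
    parent
        Mapping from each non-root node label to its parent label (the
        parent is :data:`ROOT` or another node in the mapping).
    """

    __slots__ = ("_parent", "_hash")

    def __init__(self, parent: Mapping[int, int]):
        parent = dict(parent)
        for v, p in parent.items():
            if v == ROOT:
                raise ValueError("the root sentinel cannot have a parent")
            if p != ROOT and p not in parent:
                raise ValueError(f"node {v} has parent {p} which is not in the tree")
        # Reachability from the root doubles as the cycle check: in a
        # functional graph every node either reaches ROOT or lies on a cycle.
        for v in parent:
            seen = set()
            node = v
            while node != ROOT:
                if node in seen:
                    raise ValueError(f"cycle detected through node {v}")
                seen.add(node)
                node = parent[node]
        self._parent = parent
        self._hash = hash(frozenset(parent.items()))

    # -- basic accessors -------------------------------------------------

    @property
    def node_count(self) -> int:
        """Number of non-root (mutation) nodes."""
        return len(self._parent)

    @property
    def labels(self) -> tuple[int, ...]:
        return tuple(sorted(self._parent))

    def parent_of(self, v: int) -> int:
        return self._parent[v]

    def parent_items(self) -> Iterator[tuple[int, int]]:
        return iter(self._parent.items())

    def __contains__(self, v: int) -> bool:
        return v in self._parent

    def children_of(self, u: int) -> tuple[int, ...]:
        return tuple(sorted(v for v, p in self._parent.items() if p == u))

    def children_map(self) -> dict[int, list[int]]:
        out: dict[int, list[int]] = {ROOT: []}
        for v in sorted(self._parent):
            out.setdefault(v, [])
        for v in sorted(self._parent):
            out.setdefault(self._parent[v], []).append(v)
        return out

    def ancestors_of(self, v: int) -> tuple[int, ...]:
        """Strict ancestors of ``v``, nearest first, excluding the root."""
        out = []
        node = self._parent[v]
        while node != ROOT:
            out.append(node)
            node = self._parent[node]
        return tuple(out)

    # -- equality / hashing ---------------------------------------------

    def __eq__(self, other: object) -> bool:
        return isinstance(other, MutationTree) and self._parent == other._parent

    def __hash__(self) -> int:
        return self._hash

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"MutationTree({self._parent!r})"

    # -- conversions -----------------------------------------------------

    def parent_vector(self, n: int | None = None) -> np.ndarray:
        """Parent vector for a tree over labels ``1..n``; entry ``j-1`` is
        the parent of mutation ``j`` (0 = root)."""
        if n is None:
            n = self.node_count
        if set(self._parent) != set(range(1, n + 1)):
            raise ValueError("parent_vector requires contiguous labels 1..n")
        return np.array([self._parent[j] for j in range(1, n + 1)], dtype=np.int64)

    @classmethod
    def from_parent_vector(cls, vec: Sequence[int]) -> "MutationTree":
        return cls({j + 1: int(p) for j, p in enumerate(vec)})

    def restrict(self, labels: Iterable[int]) -> "MutationTree":
        """Restriction to a label subset: each kept node is re-parented to
        its nearest kept ancestor (or the root)."""
        keep = set(labels)
        if not keep <= set(self._parent):
            raise ValueError("restriction labels must be nodes of the tree")
        parent = {}
        for v in keep:
            p = self._parent[v]
            while p != ROOT and p not in keep:
                p = self._parent[p]
            parent[v] = p
        return MutationTree(parent)


@dataclass(frozen=True)
class TreeExtension:
    """Placement of one new mutation into an existing tree.

    The new node ``new_mutation`` becomes a child of ``attach_node`` and
    adopts the subset ``adopted_children`` of ``attach_node``'s current
    children.  Equivalently this fixes the appended ancestor column
    (ancestors of ``attach_node`` plus ``attach_node``) and descendant row
    (the adopted subtrees) of the extended genotype matrix.
    """

    attach_node: int
    adopted_children: frozenset[int]
    new_mutation: int


def tree_to_genotype(tree: MutationTree, order: Sequence[int] | None = None) -> np.ndarray:
    """Binary genotype matrix of ``tree``.

    ``B[j, v] == 1`` iff mutation ``order[j]`` is ``order[v]`` or one of its
    ancestors.  ``order`` defaults to ascending label order; each column is
    filled by one walk to the root, i.e. linear in the column's depth.
    """
    if order is None:
        order = tree.labels
    order = list(order)
    if set(order) != set(tree.labels) or len(order) != tree.node_count:
        raise ValueError("order must be a permutation of the tree's labels")
    idx = {lab: i for i, lab in enumerate(order)}
    n = len(order)
    B = np.zeros((n, n), dtype=np.uint8)
    for lab in order:
        v = idx[lab]
        B[v, v] = 1
        for anc in tree.ancestors_of(lab):
            B[idx[anc], v] = 1
    return B


def is_perfect_phylogeny(B: np.ndarray) -> bool:
    """True iff ``B`` is realizable as a mutation-tree genotype matrix.

    Row ``j`` of ``B`` is the set of clones carrying mutation ``j`` — the
    subtree below ``j`` — so the rows must form a laminar family (every
    pair nested or disjoint).  In addition the diagonal must be all ones
    (each clone carries its own defining mutation) and ancestry must be
    antisymmetric (``B[u, v] == B[v, u] == 1`` for ``u != v`` would make
    two mutations ancestors of each other).

    Raises ``ValueError`` for non-square or non-binary input.
    """
    B = np.asarray(B)
    if B.ndim != 2 or B.shape[0] != B.shape[1]:
        raise ValueError("genotype matrix must be square")
    if not np.isin(B, (0, 1)).all():
        raise ValueError("genotype matrix must be binary")
    if not (np.diag(B) == 1).all():
        return False
    Bi = B.astype(np.int64)
    off = ~np.eye(B.shape[0], dtype=bool)
    if ((Bi == 1) & (Bi.T == 1) & off).any():
        return False
    inter = Bi @ Bi.T  # |rows(u) ∩ rows(w)| as clone sets
    sizes = np.diag(inter)
    ok = (inter == 0) | (inter == sizes[:, None]) | (inter == sizes[None, :])
    return bool(ok.all())


def genotype_to_tree(B: np.ndarray, labels: Sequence[int] | None = None) -> MutationTree:
    """Unique mutation tree whose genotype matrix is ``B``.

    The parent of mutation ``v`` is the ancestor ``u != v`` with
    ``B[u, v] == 1`` having the largest ancestor set; if none exists the
    parent is the root.  Non-perfect-phylogeny input is rejected.
    """
    B = np.asarray(B)
    if not is_perfect_phylogeny(B):
        raise ValueError("matrix is not a perfect-phylogeny genotype matrix")
    n = B.shape[0]
    if labels is None:
        labels = list(range(1, n + 1))
    colsize = B.sum(axis=0)
    parent = {}
    for v in range(n):
        anc = [u for u in range(n) if u != v and B[u, v]]
        if anc:
            best = max(anc, key=lambda u: (colsize[u], -u))
            parent[labels[v]] = labels[best]
        else:
            parent[labels[v]] = ROOT
    tree = MutationTree(parent)
    if not np.array_equal(tree_to_genotype(tree, order=labels), B):
        raise ValueError("matrix is not realizable as a mutation tree")
    return tree


def enumerate_extensions(tree: MutationTree, new_mutation: int) -> list[TreeExtension]:
    """All valid placements of ``new_mutation`` into ``tree``.

    One extension per (node ``u``, subset ``S`` of ``u``'s children); the
    count is therefore sum over nodes of ``2**len(children)``.  Order is
    deterministic: root first then nodes by ascending label, and child
    subsets in lexicographic bitmask order over the sorted child list.
    """
    if new_mutation in tree or new_mutation == ROOT:
        raise ValueError(f"label {new_mutation} already in tree (or is the root)")
    exts = []
    for u in (ROOT, *tree.labels):
        kids = tree.children_of(u)
        for mask in range(1 << len(kids)):
            S = frozenset(kids[i] for i in range(len(kids)) if mask >> i & 1)
            exts.append(TreeExtension(u, S, new_mutation))
    return exts


def count_extensions(tree: MutationTree) -> int:
    """Number of valid placements of a new mutation (the uniform-prior
    normalizer tau), without materializing them."""
    total = 0
    for u in (ROOT, *tree.labels):
        total += 1 << len(tree.children_of(u))
    return total


def apply_extension(tree: MutationTree, ext: TreeExtension) -> MutationTree:
    """Apply ``ext`` to ``tree``, returning a new tree; the input tree is
    unmodified.  Stale extensions (nodes missing) are rejected."""
    if ext.new_mutation in tree:
        raise ValueError(f"mutation {ext.new_mutation} already placed")
    if ext.attach_node != ROOT and ext.attach_node not in tree:
        raise ValueError(f"attach node {ext.attach_node} not in tree")
    kids = set(tree.children_of(ext.attach_node))
    if not ext.adopted_children <= kids:
        raise ValueError("adopted children are not children of the attach node")
    parent = dict(tree.parent_items())
    parent[ext.new_mutation] = ext.attach_node
    for c in ext.adopted_children:
        parent[c] = ext.new_mutation
    return MutationTree(parent)


# Pairwise evolutionary relationship codes.
ANCESTRAL = 0    # i lies on the root->j path
DESCENDANT = 1   # j lies on the root->i path
BRANCHED = 2     # neither; i and j are in different branches
COCLUSTER = 3    # same node (only on the diagonal for mutation trees)

N_RELATIONS = 4


def pairwise_relations(tree: MutationTree, n_mutations: int | None = None) -> np.ndarray:
    """``n x n`` matrix of relationship codes between ordered mutation pairs.

    Requires a complete tree over labels ``1..n``; partial trees are
    rejected because pairwise relations of unplaced mutations are undefined.
    """
    n = tree.node_count if n_mutations is None else n_mutations
    if set(tree.labels) != set(range(1, n + 1)):
        raise ValueError("pairwise_relations requires a complete tree over 1..n")
    B = tree_to_genotype(tree, order=range(1, n + 1)).astype(bool)
    rel = np.full((n, n), BRANCHED, dtype=np.int8)
    rel[B & ~np.eye(n, dtype=bool)] = ANCESTRAL
    rel[(B & ~np.eye(n, dtype=bool)).T] = DESCENDANT
    np.fill_diagonal(rel, COCLUSTER)
    return rel
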