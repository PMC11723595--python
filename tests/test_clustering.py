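"""Phylogeny-aware agglomerative clustering and GIC model selection."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from orchard import (
    MutationTree,
    agglomerate,
    clustering_log_likelihood,
    gic_select,
    infer_clone_tree,
    simulate_clustered,
    simulate_reads,
    tree_to_genotype,
    ward_distance,
)
from orchard.clustering import pooled_clone_vafs
from orchard.likelihood import binom_logpmf
from orchard.phylo_model import ROOT

from conftest import make_dataset


class TestWardDistance:
    def test_singletons(self):
        sizes = {1: 1, 2: 1}
        means = {1: np.array([0.5]), 2: np.array([0.3])}
        assert ward_distance(1, 2, sizes, means) == pytest.approx(0.02)

    def test_identical_means_zero(self):
        sizes = {1: 3, 2: 5}
        means = {1: np.array([0.4, 0.2]), 2: np.array([0.4, 0.2])}
        assert ward_distance(1, 2, sizes, means) == 0.0

    def test_size_factor_doubles_for_pairs(self):
        means = {1: np.array([0.5]), 2: np.array([0.3])}
        d1 = ward_distance(1, 2, {1: 1, 2: 1}, means)
        d2 = ward_distance(1, 2, {1: 2, 2: 2}, means)
        assert d2 == pytest.approx(2 * d1)

    def test_non_adjacent_pair_rejected(self):
        sizes = {1: 1, 2: 1, 3: 1}
        means = {k: np.zeros(1) for k in sizes}
        parent = {1: ROOT, 2: 1, 3: 2}
        with pytest.raises(ValueError):
            ward_distance(1, 3, sizes, means, parent)
        # parent/child and root-sibling pairs are adjacent
        ward_distance(1, 2, sizes, means, parent)
        ward_distance(1, 3, sizes, means, {1: ROOT, 2: 1, 3: ROOT})


class TestAgglomerate:
    def test_chain_merges_closest_adjacent_pair_first(self):
        tree = MutationTree({1: ROOT, 2: 1, 3: 2})
        F = np.array([[0.9], [0.85], [0.3]])
        path = agglomerate(tree, F)
        second = path.states[1]
        assert frozenset([1, 2]) in second.members
        # merged mean is the size-weighted average
        i = second.members.index(frozenset([1, 2]))
        assert second.means[i] == pytest.approx([0.875])

    def test_path_has_all_cluster_counts(self):
        tree = MutationTree({1: ROOT, 2: 1, 3: 1, 4: ROOT, 5: 4})
        path = agglomerate(tree, np.linspace(0.9, 0.1, 5)[:, None])
        assert [s.n_clones for s in path.states] == [5, 4, 3, 2, 1]

    def test_star_merges_root_siblings(self):
        tree = MutationTree({1: ROOT, 2: ROOT, 3: ROOT})
        F = np.array([[0.5], [0.49], [0.1]])
        path = agglomerate(tree, F)
        assert frozenset([1, 2]) in path.states[1].members
        assert path.states[-1].n_clones == 1

    def test_only_child_pairs_merge_before_others(self):
        # 2 is 1's only child and much farther from 1 than the root
        # siblings are from each other; the only-child rule still wins
        tree = MutationTree({1: ROOT, 2: 1, 3: ROOT, 4: ROOT})
        F = np.array([[0.9], [0.2], [0.5], [0.5]])
        path = agglomerate(tree, F)
        assert frozenset([1, 2]) in path.states[1].members

    def test_clones_connected_in_source_tree_up_to_the_root(self, rng):
        """Every clone is an edge-contracted node set: it has a single head
        (one member whose tree-parent lies outside the clone), except that
        several heads are allowed when they all hang off the germline root."""
        parent = {1: ROOT}
        for j in range(2, 10):
            parent[j] = int(rng.integers(0, j))
        tree = MutationTree(parent)
        F = rng.uniform(0, 1, (9, 3))
        path = agglomerate(tree, F)
        for state in path.states:
            for clone in state.members:
                heads = [v for v in clone if tree.parent_of(v) not in clone]
                assert len(heads) == 1 or all(tree.parent_of(h) == ROOT for h in heads)


class TestClusteringLikelihood:
    def test_singleton_clones_reduce_to_per_mutation_pmfs(self):
        data = make_dataset([[10], [40]], [[100], [100]], 1.0)
        Z = np.eye(2, dtype=int)
        lam = pooled_clone_vafs(data, [frozenset([1]), frozenset([2])])
        expected = binom_logpmf(data.var_reads, data.total_reads,
                                np.array([[0.1], [0.4]])).sum()
        assert clustering_log_likelihood(data, Z, lam) == pytest.approx(expected)

    def test_pooling_identical_counts_keeps_lambda(self):
        data = make_dataset([[30], [30]], [[100], [100]], 1.0)
        lam = pooled_clone_vafs(data, [frozenset([1, 2])])
        assert lam[0, 0] == pytest.approx(0.3)

    def test_merging_dissimilar_vafs_lowers_likelihood(self):
        data = make_dataset([[10], [90]], [[100], [100]], 1.0)
        separate = clustering_log_likelihood(
            data, np.eye(2, dtype=int),
            pooled_clone_vafs(data, [frozenset([1]), frozenset([2])]))
        merged = clustering_log_likelihood(
            data, np.ones((2, 1), dtype=int),
            pooled_clone_vafs(data, [frozenset([1, 2])]))
        assert merged < separate

    def test_empty_clone_rejected(self):
        data = make_dataset([[10]], [[100]])
        with pytest.raises(ValueError):
            clustering_log_likelihood(data, np.array([[1, 0]]), np.zeros((2, 1)))


class TestGicSelection:
    def test_single_mutation_trivially_one_clone(self):
        data = make_dataset([[10]], [[100]])
        tree = MutationTree({1: ROOT})
        ct = infer_clone_tree(tree, data)
        assert ct.n_clones == 1

    def test_planted_blocks_recovered_exactly(self, rng):
        """Noise-free block frequencies: the inferred clones match the
        planted assignment with ARI = 1."""
        assign = np.repeat([0, 1, 2], 3)
        clone_f = np.array([[0.9, 0.8], [0.55, 0.5], [0.2, 0.15]])
        F = clone_f[assign]
        # chain tree: blocks are contiguous
        tree = MutationTree({1: ROOT, **{j: j - 1 for j in range(2, 10)}})
        N = np.full(F.shape, 2000)
        b = np.round(N * 0.5 * F).astype(int)
        data = make_dataset(b, N, 0.5)
        ct = infer_clone_tree(tree, data)
        assert adjusted_rand_score(assign, ct.assignment) == 1.0

    def test_deep_distinct_vafs_select_singletons(self):
        rng = np.random.default_rng(3)
        n = 6
        tree = MutationTree({1: ROOT, **{j: j - 1 for j in range(2, n + 1)}})
        U = np.full((n, 2), 0.15)
        B = tree_to_genotype(tree, order=range(1, n + 1)).astype(float)
        F = B @ U
        data = simulate_reads(F, 1e5, 0.5, rng)
        ct = infer_clone_tree(tree, data)
        assert ct.n_clones == n

    def test_gic_curve_reported_for_all_clusterings(self):
        gt = simulate_clustered(8, 3, 4, depth=500, seed=2)
        ct = infer_clone_tree(gt.tree, gt.data)
        assert len(ct.gic_table) == 8
        assert sorted(c for c, _, _ in ct.gic_table) == list(range(1, 9))


class TestInferCloneTree:
    def test_clone_count_never_exceeds_mutations(self):
        gt = simulate_clustered(10, 4, 5, depth=300, seed=9)
        ct = infer_clone_tree(gt.tree, gt.data)
        assert 1 <= ct.n_clones <= 10
        assert (ct.Z.sum(axis=1) == 1).all()

    def test_clone_tree_edges_are_contractions_of_input_edges(self):
        gt = simulate_clustered(12, 4, 5, depth=300, seed=10)
        ct = infer_clone_tree(gt.tree, gt.data)
        clones = [set(np.flatnonzero(ct.Z[:, i]) + 1) for i in range(ct.n_clones)]
        for i, p in enumerate(ct.parent):
            if p < 0:
                continue
            # some mutation in clone i has its tree-parent in clone p
            assert any(gt.tree.parent_of(v) in clones[p] for v in clones[i])
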