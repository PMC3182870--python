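import itertools

import numpy as np
import pytest

import ngforest as ngf
from ngforest.dataset import LabeledExpression, bootstrap, derive_seed
from ngforest.graph_io import ProteinNetwork
from ngforest.tree import (
    NGFConfig,
    best_split,
    gini_impurity,
    grow_tree,
    iter_paths,
    predict_proba,
    sample_expansion_candidates,
    sample_root_candidates,
    tree_genes,
    tree_to_json,
)


def brute_force_best_split(data, sample_idx, candidates):
    """Independent exhaustive scorer over every (gene, midpoint) pair."""
    sample_idx = np.asarray(sample_idx)
    n = sample_idx.size
    y = data.y[sample_idx]

    def gini(labels):
        if len(labels) == 0:
            return 0.0
        _, c = np.unique(labels, return_counts=True)
        p = c / c.sum()
        return 1.0 - float((p**2).sum())

    parent = gini(y)
    best = None  # (improvement, gene, threshold)
    for gene in sorted(candidates):
        v = data.gene_values(gene)[sample_idx]
        for lo, hi in zip(sorted(set(v))[:-1], sorted(set(v))[1:]):
            thr = (lo + hi) / 2.0
            left, right = y[v < thr], y[v >= thr]
            imp = parent - len(left) / n * gini(left) - len(right) / n * gini(right)
            if best is None or imp > best[0] + 1e-12:
                best = (imp, gene, thr)
    if best is None or parent == 0.0:
        return None
    return best[1], best[2], best[0]


def random_instance(rng, n_genes=6, n_samples=12):
    return LabeledExpression(
        genes=[f"g{i}" for i in range(n_genes)],
        samples=[f"s{i}" for i in range(n_samples)],
        values=rng.normal(size=(n_genes, n_samples)),
        labels=np.array(rng.choice(["a", "b"], size=n_samples), dtype=object),
    )


class TestGini:
    @pytest.mark.parametrize(
        "counts,expected",
        [((5, 5), 0.5), ((10, 0), 0.0), ((3, 1), 0.375), ((1, 1, 1), 2 / 3)],
    )
    def test_known_values(self, counts, expected):
        assert gini_impurity(counts) == pytest.approx(expected)

    def test_empty_node_rejected(self):
        with pytest.raises(ValueError):
            gini_impurity((0, 0))


class TestBestSplit:
    def test_perfect_split_at_midpoint(self):
        data = LabeledExpression(
            genes=["x"], samples=list("pqrs"),
            values=np.array([[1.0, 2.0, 8.0, 9.0]]),
            labels=np.array(["a", "a", "b", "b"], dtype=object),
        )
        gene, thr, imp = best_split(data, np.arange(4), {"x"})
        assert (gene, thr, imp) == ("x", 5.0, pytest.approx(0.5))

    def test_pure_node_returns_none(self):
        data = LabeledExpression(
            genes=["x"], samples=["p", "q", "r"],
            values=np.array([[1.0, 2.0, 3.0]]),
            labels=np.array(["a", "a", "b"], dtype=object),
        )
        assert best_split(data, np.array([0, 1]), {"x"}) is None

    def test_empty_candidates_returns_none(self):
        data = random_instance(np.random.default_rng(0))
        assert best_split(data, np.arange(12), set()) is None

    def test_agrees_with_brute_force_on_random_instances(self):
        for trial in range(50):
            rng = np.random.default_rng(1000 + trial)
            data = random_instance(rng)
            if len(set(data.labels)) < 2:
                continue
            got = best_split(data, np.arange(12), set(data.genes))
            want = brute_force_best_split(data, np.arange(12), set(data.genes))
            if want is None:
                assert got is None
                continue
            assert got[0] == want[0] and got[1] == pytest.approx(want[1])
            assert got[2] == pytest.approx(want[2], abs=1e-12)

    def test_tie_break_prefers_smaller_gene_then_threshold(self):
        # two identical genes: the lexicographically smaller one must win
        data = LabeledExpression(
            genes=["gB", "gA"], samples=list("pqrs"),
            values=np.array([[1.0, 2.0, 8.0, 9.0], [1.0, 2.0, 8.0, 9.0]]),
            labels=np.array(["a", "a", "b", "b"], dtype=object),
        )
        gene, thr, _ = best_split(data, np.arange(4), {"gA", "gB"})
        assert gene == "gA" and thr == 5.0


def star_network(center="H", n_leaves=8):
    return ProteinNetwork([(center, f"L{i}") for i in range(n_leaves)])


class TestRootCandidates:
    def _net(self):
        # 40 hub genes (degree >= 5) + 60 low-degree genes, 100 measured total
        edges = []
        hubs = [f"h{i:02d}" for i in range(40)]
        for i, h in enumerate(hubs):
            for j in range(1, 6):
                edges.append((h, hubs[(i + j) % 40]))
        others = [f"o{i:02d}" for i in range(60)]
        edges += [(others[i], others[i + 1]) for i in range(59)]
        return ProteinNetwork(edges), set(hubs) | set(others)

    def test_size_is_sqrt_of_measured(self):
        net, measured = self._net()
        cfg = NGFConfig(min_root_degree=5)
        cands = sample_root_candidates(net, measured, cfg, seed=0)
        assert len(cands) == 10  # floor(sqrt(100))
        assert all(net.degree(g) >= 5 for g in cands)

    def test_small_eligible_pool_returned_whole(self):
        net = star_network(n_leaves=6)
        measured = net.nodes | {f"x{i}" for i in range(94)}
        cfg = NGFConfig(min_root_degree=5)
        assert sample_root_candidates(net, measured, cfg, seed=1) == {"H"}

    def test_no_eligible_gene_suggests_lowering_k(self):
        net = ProteinNetwork([("A", "B")])
        with pytest.raises(ValueError, match="min_root_degree"):
            sample_root_candidates(net, {"A", "B"}, NGFConfig(min_root_degree=5), seed=0)

    def test_uniform_over_eligible(self):
        net, measured = self._net()
        cfg = NGFConfig(min_root_degree=5)
        counts = {g: 0 for g in measured if net.degree(g) >= 5}
        n_seeds = 1000
        for s in range(n_seeds):
            for g in sample_root_candidates(net, measured, cfg, seed=s):
                counts[g] += 1
        expected = 10 / 40  # draws per seed / eligible pool
        se = np.sqrt(expected * (1 - expected) / n_seeds)
        for g, c in counts.items():
            assert abs(c / n_seeds - expected) < 4 * se, g


class TestExpansionCandidates:
    def test_pool_restricted_to_unvisited_neighbors(self):
        net = ProteinNetwork([("A", "B"), ("A", "C")])
        cfg = NGFConfig()
        out = sample_expansion_candidates(net, {"A"}, {"A", "C"}, cfg, seed=0)
        assert out <= {"B"}

    def test_exhausted_pool_gives_empty_set(self):
        net = ProteinNetwork([("A", "B")])
        out = sample_expansion_candidates(net, {"A"}, {"A", "B"}, NGFConfig(), seed=0)
        assert out == set()

    def test_first_draw_proportional_to_shared_edges(self):
        # X shares 3 edges with the tree {T1,T2,T3}; Y shares 1
        net = ProteinNetwork(
            [("T1", "X"), ("T2", "X"), ("T3", "X"), ("T1", "Y"), ("T1", "T2"), ("T2", "T3")]
        )
        cfg = NGFConfig(candidate_size_rule=lambda n: 1)
        tree = {"T1", "T2", "T3"}
        hits = {"X": 0, "Y": 0}
        n_seeds = 10_000
        for s in range(n_seeds):
            (g,) = sample_expansion_candidates(net, tree, tree, cfg, seed=s)
            hits[g] += 1
        ratio = hits["X"] / hits["Y"]
        # expected 3:1; binomial sampling error at n=10,000 is ~ +/-0.17 on the ratio
        assert 2.5 < ratio < 3.5


class TestGrowTree:
    def _world(self, seed=0, n=80):
        rng = np.random.default_rng(seed)
        net = star_network("H", 8)
        genes = sorted(net.nodes)
        values = rng.normal(size=(len(genes), n))
        hub = genes.index("H")
        labels = np.where(values[hub] > 0, "pos", "neg").astype(object)
        data = LabeledExpression(genes, [f"s{i}" for i in range(n)], values, labels)
        return net, data

    def test_separating_hub_gives_depth_one_tree(self):
        net, data = self._world()
        cfg = NGFConfig(epsilon=0.01, min_root_degree=5, candidate_size_rule=lambda n: n)
        split = bootstrap(data, seed=1)
        tree = grow_tree(data, split, net, cfg, seed=2)
        assert tree.gene == "H"
        # both children pure on the in-bag sample
        for leaf in (tree.left, tree.right):
            if leaf.is_leaf:
                assert (leaf.class_counts == 0).any()

    def test_epsilon_one_gives_single_leaf(self):
        net, data = self._world()
        cfg = NGFConfig(epsilon=1.0, min_root_degree=5)
        tree = grow_tree(data, bootstrap(data, 1), net, cfg, seed=2)
        assert tree.is_leaf

    def test_gene_at_most_once_per_path(self, small_forest):
        for tree in small_forest.trees:
            for path, _leaf in iter_paths(tree):
                genes = [g for g, _t, _r in path]
                assert len(genes) == len(set(genes))

    def test_tested_genes_connected_in_network(self, small_forest, and_not_world):
        net, _, _ = and_not_world
        for tree in small_forest.trees:
            assert net.is_connected_subset(tree_genes(tree))

    def test_every_split_improves_by_at_least_epsilon(self, small_forest, and_not_world):
        _, data, _ = and_not_world
        eps = small_forest.config.epsilon
        for tree, split in zip(small_forest.trees[:40], small_forest.splits[:40]):
            _assert_monotone(tree, data, split.in_bag, eps)

    def test_deterministic_serialization(self):
        net, data = self._world()
        cfg = NGFConfig(epsilon=0.01, min_root_degree=5)
        t1 = grow_tree(data, bootstrap(data, 9), net, cfg, seed=5)
        t2 = grow_tree(data, bootstrap(data, 9), net, cfg, seed=5)
        assert tree_to_json(t1) == tree_to_json(t2)


def _assert_monotone(node, data, idx, eps):
    idx = np.asarray(idx)
    if node.is_leaf:
        return
    y = data.y[idx]
    n = idx.size
    v = data.gene_values(node.gene)[idx]
    left, right = idx[v < node.threshold], idx[v >= node.threshold]

    def gini(i):
        c = np.bincount(data.y[i], minlength=data.n_classes)
        p = c / c.sum()
        return 1 - (p**2).sum()

    imp = gini(idx) - left.size / n * gini(left) - right.size / n * gini(right)
    assert imp >= eps - 1e-12
    _assert_monotone(node.left, data, left, eps)
    _assert_monotone(node.right, data, right, eps)


class TestPredictProba:
    def test_leaf_proportions(self, two_class_leaf_tree):
        p = predict_proba(two_class_leaf_tree, {"A": 0.0, "B": 5.0})
        np.testing.assert_allclose(p, [1.0, 0.0])
        p = predict_proba(two_class_leaf_tree, {"A": 0.0, "B": 0.0})
        np.testing.assert_allclose(p, [1 / 7, 6 / 7])

    def test_single_leaf_gives_prior(self):
        from ngforest.tree import TreeNode

        tree = TreeNode(class_counts=np.array([3, 1]))
        np.testing.assert_allclose(predict_proba(tree, {}), [0.75, 0.25])

    def test_missing_gene_on_path_raises(self, two_class_leaf_tree):
        with pytest.raises(KeyError, match="B"):
            predict_proba(two_class_leaf_tree, {"A": 0.0})
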