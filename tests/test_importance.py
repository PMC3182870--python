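import numpy as np
import pytest

import ngforest as ngf
from ngforest.dataset import derive_seed
from ngforest.forest import Forest, build_forest
from ngforest.graph_io import ProteinNetwork
from ngforest.importance_modules import (
    PairRecord,
    compute_importances,
    consensus_modules,
    empirical_fdr,
    gene_importance,
    null_distribution,
    pair_beats_singles,
    pair_beats_singles_batch,
    pair_importance,
)
from ngforest.tree import NGFConfig


@pytest.fixture(scope="module")
def imp_table(small_forest, and_not_world):
    _, data, _ = and_not_world
    return compute_importances(small_forest, data, seed=301)


class TestGeneImportance:
    def test_unused_gene_scores_exactly_zero(self, and_not_world):
        net, data, _ = and_not_world
        tiny = build_forest(data, net, NGFConfig(n_trees=5, seed=91))
        unused = set(data.genes) - set(tiny.gene_occurrence)
        assert unused  # 5 trees cannot touch all 32 genes
        table = compute_importances(tiny, data, seed=13, with_pairs=False)
        for g in unused:
            assert table.gene_scores[g] == 0.0

    def test_identity_permutation_gives_zero(self, small_forest, and_not_world):
        _, data, _ = and_not_world
        identity = lambda _rng, values: values
        score = gene_importance(small_forest, data, "A", seed=1, permuter=identity)
        assert score == 0.0

    def test_planted_genes_outrank_noise(self, imp_table):
        scores = imp_table.gene_scores
        noise_best = max(v for g, v in scores.items() if g not in ("A", "B"))
        assert scores["A"] > noise_best and scores["B"] > noise_best

    def test_unknown_gene_rejected(self, small_forest, and_not_world):
        _, data, _ = and_not_world
        with pytest.raises(KeyError):
            gene_importance(small_forest, data, "NOPE", seed=0)

    def test_invariant_to_tree_processing_order(self, small_forest, and_not_world, imp_table):
        _, data, _ = and_not_world
        reversed_forest = Forest(
            trees=list(reversed(small_forest.trees)),
            splits=list(reversed(small_forest.splits)),
            config=small_forest.config,
            classes=small_forest.classes,
            target_class=small_forest.target_class,
        )
        # per-tree permutations are keyed by the original tree index, so
        # compare against a fresh sweep whose seeds follow the reversed order
        rev = compute_importances(reversed_forest, data, seed=301, with_pairs=False)
        n = small_forest.n_trees
        # means must agree up to the per-tree permutation draws: check the
        # strongest signal genes, whose scores are dominated by signal not draws
        assert rev.gene_scores["A"] == pytest.approx(imp_table.gene_scores["A"], abs=0.02)
        assert rev.gene_scores["B"] == pytest.approx(imp_table.gene_scores["B"], abs=0.02)


class TestPairImportance:
    def test_planted_pair_beats_members_conditionally(self, imp_table):
        rec = imp_table.pair_records[frozenset(("A", "B"))]
        members = rec.member_conditional()
        assert rec.mean_conditional > max(members.values())

    def test_pair_never_cooccurring_scores_zero(self, imp_table, small_forest, and_not_world):
        _, data, _ = and_not_world
        import itertools

        # any measured pair absent from every tree has no record and mean 0
        absent = next(
            frozenset(p)
            for p in itertools.combinations(data.genes, 2)
            if frozenset(p) not in small_forest.pair_occurrence
        )
        assert absent not in imp_table.pair_records
        assert imp_table.pair_scores.get(absent, 0.0) == 0.0

    def test_identical_genes_rejected(self, small_forest, and_not_world):
        _, data, _ = and_not_world
        with pytest.raises(ValueError):
            pair_importance(small_forest, data, ("A", "A"), seed=0)

    def test_identity_permutation_zero_for_pairs(self, small_forest, and_not_world):
        _, data, _ = and_not_world
        identity = lambda _rng, values: values
        table = compute_importances(small_forest, data, seed=11, permuter=identity)
        assert all(v == 0.0 for v in table.pair_scores.values())


class TestNullDistribution:
    def test_single_run_shapes_and_reproducibility(self, and_not_world):
        net, data, _ = and_not_world
        cfg = NGFConfig(n_trees=30, seed=2)
        g1, p1 = null_distribution(data, net, cfg, n_runs=1, tree_factor=1, seed=5)
        g2, p2 = null_distribution(data, net, cfg, n_runs=1, tree_factor=1, seed=5)
        assert g1 == g2 and p1 == p2
        assert len(g1) == 1 and len(g1[0]) == data.n_genes

    def test_null_gene_scores_centered_near_zero(self, and_not_world):
        net, data, _ = and_not_world
        cfg = NGFConfig(n_trees=40, seed=3)
        null_gene, _ = null_distribution(data, net, cfg, n_runs=8, tree_factor=1, seed=17)
        scores = np.concatenate([np.asarray(r) for r in null_gene])
        se = scores.std(ddof=1) / np.sqrt(scores.size)
        assert abs(scores.mean()) < 2 * se + 1e-3


class TestEmpiricalFDR:
    def test_score_above_all_null_gets_zero(self):
        fdr = empirical_fdr({"x": 10.0, "y": 0.0}, [[1.0, 0.5], [0.7, 0.2]])
        assert fdr["x"] == 0.0

    def test_observed_equal_to_null_run_gives_one_everywhere(self):
        scores = {f"f{i}": float(i) for i in range(10)}
        fdr = empirical_fdr(scores, [list(scores.values())])
        assert all(v == 1.0 for v in fdr.values())

    def test_monotone_non_increasing_in_score(self):
        rng = np.random.default_rng(0)
        obs = {f"f{i}": float(v) for i, v in enumerate(rng.normal(size=50))}
        null = [list(rng.normal(size=50)) for _ in range(5)]
        fdr = empirical_fdr(obs, null)
        ranked = sorted(obs, key=obs.get)
        vals = [fdr[f] for f in ranked]
        assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_empty_observed_rejected(self):
        with pytest.raises(ValueError):
            empirical_fdr({}, [[1.0]])

    def test_planted_shift_detected_with_fdr_control(self):
        rng = np.random.default_rng(42)
        detected, false_hits, n_rejections, n_sims = 0, 0, 0, 50
        for _ in range(n_sims):
            null = [list(rng.normal(size=200)) for _ in range(10)]
            obs_vals = rng.normal(size=200)
            obs_vals[:10] += 5.0  # planted shift, well clear of the null tail
            obs = {f"f{i}": float(v) for i, v in enumerate(obs_vals)}
            fdr = empirical_fdr(obs, null)
            detected += all(fdr[f"f{i}"] < 0.05 for i in range(10))
            false_hits += sum(fdr[f"f{i}"] < 0.05 for i in range(10, 200))
            n_rejections += sum(v < 0.05 for v in fdr.values())
        assert detected >= 45  # >= 90% of simulations recover all planted features
        # false discoveries stay near the nominal 5% of all rejections
        assert false_hits <= 0.1 * n_rejections


class TestPairBeatsSingles:
    def _record(self, pair_inc, a_inc, b_inc):
        return PairRecord(
            pair=frozenset(("a", "b")),
            trees=list(range(len(pair_inc))),
            pair_increase=list(pair_inc),
            member_increase={"a": list(a_inc), "b": list(b_inc)},
        )

    def test_identical_increases_not_significant(self):
        inc = [0.1] * 20
        assert pair_beats_singles(self._record(inc, inc, inc)) == 1.0

    def test_strictly_greater_everywhere_significant(self):
        rec = self._record([0.3] * 50, [0.1] * 50, [0.05] * 50)
        assert pair_beats_singles(rec) < 1e-6

    def test_too_few_trees_not_significant(self):
        rec = self._record([0.5] * 4, [0.1] * 4, [0.1] * 4)
        assert pair_beats_singles(rec) == 1.0

    def test_type_one_error_controlled_for_additive_signal(self):
        rng = np.random.default_rng(7)
        n_sig = 0
        for _ in range(100):
            a = rng.normal(0.1, 0.05, size=30)
            b = rng.normal(0.05, 0.05, size=30)
            pair = np.maximum(a, b) + rng.normal(0, 0.01, size=30)  # adds nothing systematic
            rec = self._record(pair, a, b)
            out = pair_beats_singles_batch({rec.pair: rec}, alpha=0.05)
            n_sig += out[rec.pair][2]
        assert n_sig <= 10  # one-sided test at 5% with slack for MC noise


class TestConsensusModules:
    def _forest_with_tree_sets(self, memberships, n_trees):
        """Build a stub forest whose tree gene sets are given explicitly."""
        from ngforest.dataset import BootstrapSplit
        from ngforest.tree import TreeNode

        trees = []
        for genes in memberships:
            node = TreeNode(class_counts=np.array([1, 1]))
            for g in sorted(genes):
                node = TreeNode(gene=g, threshold=0.0, left=TreeNode(class_counts=np.array([1, 0])), right=node)
            trees.append(node)
        splits = [
            BootstrapSplit(in_bag=np.zeros(2, dtype=int), out_of_bag=np.array([1]))
            for _ in trees
        ]
        f = Forest(trees=trees, splits=splits, config=NGFConfig(n_trees=len(trees)),
                   classes=["n", "y"], target_class="y")
        from ngforest.forest import _tally

        _tally(f)
        return f

    def test_genes_sharing_all_trees_cluster_together(self):
        member = [{"A", "B"}] * 5 + [{"C"}] * 5
        net = ProteinNetwork([("A", "B"), ("B", "C")])
        f = self._forest_with_tree_sets(member, 10)
        mods = consensus_modules({"A", "B", "C"}, set(), f, net)
        by_genes = {frozenset(m.genes) for m in mods}
        assert frozenset({"A", "B"}) in by_genes

    def test_never_cooccurring_genes_get_singletons(self):
        member = [{"A"}] * 3 + [{"B"}] * 3 + [{"C"}] * 3
        net = ProteinNetwork([("A", "B"), ("B", "C")])
        f = self._forest_with_tree_sets(member, 9)
        mods = consensus_modules({"A", "B", "C"}, set(), f, net)
        assert sorted(sorted(m.genes) for m in mods) == [["A"], ["B"], ["C"]]

    def test_all_modules_connected(self, small_forest, and_not_world, imp_table):
        net, data, _ = and_not_world
        top = sorted(imp_table.gene_scores, key=imp_table.gene_scores.get, reverse=True)[:6]
        mods = consensus_modules(set(top), set(), small_forest, net, data)
        for m in mods:
            assert net.is_connected_subset(m.genes)

    def test_two_planted_modules_recovered(self):
        recovered = 0
        n_seeds = 5
        for s in range(n_seeds):
            net, data, truth = ngf.generate(ngf.two_module_scenario(seed=100 + s))
            cfg = NGFConfig(n_trees=250, seed=s)
            forest = build_forest(data, net, cfg)
            table = compute_importances(forest, data, seed=s, with_pairs=False)
            planted = {g for m in truth["modules"] for g in m["genes"]}
            mods = consensus_modules(planted, set(), forest, net, data)
            want = {frozenset(m["genes"]) for m in truth["modules"]}
            got = {frozenset(m.genes) for m in mods}
            recovered += want <= got
        assert recovered >= n_seeds - 1
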