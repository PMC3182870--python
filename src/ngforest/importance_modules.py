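"""Permutation importance, permutation-null FDR and consensus decision modules.

Importance of a gene is the mean increase in per-tree out-of-bag (OOB)
misclassification error when that gene's OOB measurements are randomly
permuted; trees that never test the gene contribute exactly 0 to the mean.
Pair importance permutes both genes (independently, by default) in trees
containing both. Significance is assessed against an empirical null built by
re-running the whole pipeline on class-label-permuted data, and gene pairs
must additionally beat their best single member in the trees where both are
present. Significant features are clustered into consensus decision modules
by affinity propagation on the Jaccard similarity of the tree sets in which
they appear; every reported module induces a connected subgraph of the
network.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import wilcoxon
from sklearn.cluster import AffinityPropagation
from statsmodels.stats.multitest import multipletests

from .dataset import LabeledExpression, derive_seed, permute_labels
from .forest import Forest, build_forest, oob_error
from .graph_io import ProteinNetwork
from .tree import NGFConfig, tree_genes

logger = logging.getLogger("ngforest")

__all__ = [
    "ImportanceTable",
    "DecisionModule",
    "gene_importance",
    "pair_importance",
    "compute_importances",
    "null_distribution",
    "empirical_fdr",
    "pair_beats_singles",
    "pair_beats_singles_batch",
    "consensus_modules",
    "importance_pipeline",
]

Pair = frozenset


@dataclass
class PairRecord:
    """Per-tree bookkeeping for one gene pair over its qualifying trees
    (trees whose gene set contains both members)."""

    pair: frozenset
    trees: list[int] = field(default_factory=list)
    pair_increase: list[float] = field(default_factory=list)
    member_increase: dict[str, list[float]] = field(default_factory=dict)

    @property
    def mean_conditional(self) -> float:
        return float(np.mean(self.pair_increase)) if self.pair_increase else 0.0

    def member_conditional(self) -> dict[str, float]:
        return {g: (float(np.mean(v)) if v else 0.0) for g, v in self.member_increase.items()}


@dataclass
class ImportanceTable:
    gene_scores: dict[str, float]
    pair_scores: dict[frozenset, float]
    pair_records: dict[frozenset, PairRecord]
    gene_tree_increase: dict[str, dict[int, float]]
    n_effective_trees: int
    null_gene_scores: list[list[float]] = field(default_factory=list)
    null_pair_scores: list[list[float]] = field(default_factory=list)
    fdr_gene: dict[str, float] = field(default_factory=dict)
    fdr_pair: dict[frozenset, float] = field(default_factory=dict)


class _FlatTree:
    """Array form of one tree restricted to its own genes and OOB samples.

    Permutation importance re-routes the same OOB samples through the same
    tree hundreds of times with one or two gene rows scrambled; flattening
    the tree into index arrays makes each re-evaluation a handful of
    vectorized operations.
    """

    def __init__(self, tree, oob: np.ndarray, data: LabeledExpression, target_code: int):
        from .tree import TreeNode  # local import to avoid cycle noise

        genes = sorted(tree_genes(tree))
        self.genes = genes
        self.local = {g: r for r, g in enumerate(genes)}
        feat, thr, left, right, leaf_call = [], [], [], [], []

        def add(node: "TreeNode") -> int:
            idx = len(feat)
            feat.append(-1)
            thr.append(0.0)
            left.append(-1)
            right.append(-1)
            leaf_call.append(-1)
            if node.is_leaf:
                counts = node.class_counts
                call = target_code if counts[target_code] == counts.max() else int(counts.argmax())
                leaf_call[idx] = call
            else:
                feat[idx] = self.local[node.gene]
                left[idx] = add(node.left)
                right[idx] = add(node.right)
            return idx

        add(tree)
        self.feat = np.asarray(feat, dtype=np.int32)
        self.thr = np.asarray(thr, dtype=float)
        self.left = np.asarray(left, dtype=np.int32)
        self.right = np.asarray(right, dtype=np.int32)
        self.leaf_call = np.asarray(leaf_call, dtype=np.int32)
        # fill thresholds in a second pass (kept out of add() for clarity)
        self._fill_thresholds(tree)
        rows = [data.gene_index[g] for g in genes]
        self.V0 = data.values[np.ix_(rows, oob)] if genes else np.empty((0, oob.size))
        self.y = data.y[oob]
        self.n = oob.size

    def _fill_thresholds(self, tree) -> None:
        stack = [(tree, 0)]
        while stack:
            node, idx = stack.pop()
            if node.is_leaf:
                continue
            self.thr[idx] = node.threshold
            stack.append((node.left, self.left[idx]))
            stack.append((node.right, self.right[idx]))

    def route_calls(self, V: np.ndarray) -> np.ndarray:
        """Class call per column of V (columns = samples, rows = local genes)."""
        ncol = V.shape[1]
        node = np.zeros(ncol, dtype=np.int32)
        cols = np.arange(ncol)
        while True:
            f = self.feat[node]
            internal = f >= 0
            if not internal.any():
                break
            go_right = V[f, cols] >= self.thr[node]
            nxt = np.where(go_right, self.right[node], self.left[node])
            node = np.where(internal, nxt, node)
        return self.leaf_call[node]

    def error(self, V: np.ndarray | None = None) -> float:
        V = self.V0 if V is None else V
        return float(np.mean(self.route_calls(V) != self.y))

    def batch_errors(self, permutations: list[np.ndarray | None]) -> np.ndarray:
        """OOB error for a batch of value matrices routed in one pass.

        Each entry is a (local genes x n) matrix or None for the unpermuted
        baseline; all are concatenated along the sample axis so the routing
        loop's cost is amortized over the whole batch.
        """
        mats = [self.V0 if V is None else V for V in permutations]
        big = np.concatenate(mats, axis=1) if self.genes else np.empty((0, self.n * len(mats)))
        calls = self.route_calls(big).reshape(len(mats), self.n)
        return (calls != self.y[None, :]).mean(axis=1)


def _permute_rows(flat: _FlatTree, genes, rng, permuter=None, joint=False) -> np.ndarray:
    V = flat.V0.copy()
    if joint:
        perm = rng.permutation(flat.n)
        for g in genes:
            V[flat.local[g]] = flat.V0[flat.local[g], perm]
        return V
    for g in genes:
        row = flat.local[g]
        V[row] = permuter(rng, flat.V0[row]) if permuter is not None else rng.permutation(flat.V0[row])
    return V


def gene_importance(
    forest: Forest, data: LabeledExpression, gene: str, seed: int, permuter=None
) -> float:
    """Mean OOB error increase from permuting one gene; unused trees count 0."""
    if gene not in data.gene_index:
        raise KeyError(f"unknown gene {gene!r}")
    table = compute_importances(forest, data, seed, with_pairs=False, permuter=permuter)
    return table.gene_scores[gene]


def pair_importance(
    forest: Forest, data: LabeledExpression, pair, seed: int, joint: bool = False
) -> tuple[float, float, dict[str, float]]:
    """(all-trees mean, conditional mean over co-occurring trees, member conditional means).

    By default both genes are permuted independently within each qualifying
    tree (destroying each marginal signal and the joint pattern); with
    ``joint=True`` a single permutation is applied to both genes, preserving
    their joint pattern while destroying the link to the labels.
    """
    a, b = sorted(pair)
    if a == b:
        raise ValueError("pair must consist of two distinct genes")
    table = compute_importances(forest, data, seed, pairs_of_interest={frozenset((a, b))}, joint=joint)
    key = frozenset((a, b))
    rec = table.pair_records.get(key, PairRecord(pair=key))
    return table.pair_scores.get(key, 0.0), rec.mean_conditional, rec.member_conditional()


def compute_importances(
    forest: Forest,
    data: LabeledExpression,
    seed: int,
    with_pairs: bool = True,
    pairs_of_interest: set[frozenset] | None = None,
    joint: bool = False,
    permuter=None,
) -> ImportanceTable:
    """Single sweep over the forest computing every gene (and pair) score.

    Equivalent to calling :func:`gene_importance` per gene but amortizes the
    per-tree routing work. Trees with no OOB samples are skipped; the mean is
    taken over the remaining trees, with 0 contributions for trees not using
    a feature (genes measured but never used score exactly 0).
    """
    import itertools

    gene_sum: dict[str, float] = {g: 0.0 for g in data.genes}
    gene_tree_increase: dict[str, dict[int, float]] = {}
    pair_sum: dict[frozenset, float] = {}
    pair_records: dict[frozenset, PairRecord] = {}
    n_eff = 0

    for i in range(forest.n_trees):
        oob = forest.splits[i].out_of_bag
        if oob.size == 0:
            continue
        n_eff += 1
        flat = _FlatTree(forest.trees[i], oob, data, forest.target_code)
        genes_i = flat.genes
        mats: list[np.ndarray | None] = [None]  # baseline first
        tags: list[tuple] = [("base",)]
        for g in genes_i:
            rng = np.random.default_rng(derive_seed(seed, f"imp:{g}", i))
            mats.append(_permute_rows(flat, [g], rng, permuter))
            tags.append(("gene", g))
        if with_pairs:
            for a, b in itertools.combinations(genes_i, 2):
                key = frozenset((a, b))
                if pairs_of_interest is not None and key not in pairs_of_interest:
                    continue
                rng = np.random.default_rng(derive_seed(seed, f"pimp:{a}|{b}", i))
                mats.append(_permute_rows(flat, (a, b), rng, permuter, joint=joint))
                tags.append(("pair", a, b))
        errors = flat.batch_errors(mats)
        base = float(errors[0])
        tree_inc: dict[str, float] = {}
        for tag, err in zip(tags[1:], errors[1:]):
            inc = float(err) - base
            if tag[0] == "gene":
                g = tag[1]
                gene_sum[g] += inc
                tree_inc[g] = inc
                gene_tree_increase.setdefault(g, {})[i] = inc
            else:
                _, a, b = tag
                key = frozenset((a, b))
                pair_sum[key] = pair_sum.get(key, 0.0) + inc
                rec = pair_records.setdefault(key, PairRecord(pair=key, member_increase={a: [], b: []}))
                rec.trees.append(i)
                rec.pair_increase.append(inc)
                rec.member_increase[a].append(tree_inc[a])
                rec.member_increase[b].append(tree_inc[b])

    if n_eff == 0:
        raise ValueError("no tree has out-of-bag samples")
    gene_scores = {g: s / n_eff for g, s in gene_sum.items()}
    pair_scores = {k: s / n_eff for k, s in pair_sum.items()}
    return ImportanceTable(
        gene_scores=gene_scores,
        pair_scores=pair_scores,
        pair_records=pair_records,
        gene_tree_increase=gene_tree_increase,
        n_effective_trees=n_eff,
    )


def null_distribution(
    data: LabeledExpression,
    net: ProteinNetwork,
    cfg: NGFConfig,
    n_runs: int = 100,
    tree_factor: int = 10,
    seed: int = 0,
    with_pairs: bool = True,
) -> tuple[list[list[float]], list[list[float]]]:
    """Per-run gene- and pair-score lists from forests on label-permuted data.

    Null forests use ``cfg.n_trees // tree_factor`` trees per run (factor
    logged); each run has independently permuted labels and its own seed.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    n_null_trees = max(1, cfg.n_trees // max(1, tree_factor))
    if n_null_trees != cfg.n_trees:
        logger.info("null runs use %d trees each (1/%d of the observed forest)", n_null_trees, tree_factor)
    null_gene, null_pair = [], []
    for r in range(n_runs):
        run_seed = derive_seed(seed, "null-run", r)
        perm = permute_labels(data, derive_seed(run_seed, "labels"))
        null_cfg = NGFConfig(
            epsilon=cfg.epsilon, min_root_degree=cfg.min_root_degree,
            n_trees=n_null_trees, candidate_size_rule=cfg.candidate_size_rule,
            seed=derive_seed(run_seed, "forest"), stratified_bootstrap=cfg.stratified_bootstrap,
        )
        f = build_forest(perm, net, null_cfg)
        table = compute_importances(f, perm, derive_seed(run_seed, "imp"), with_pairs=with_pairs)
        null_gene.append(sorted(table.gene_scores.values(), reverse=True))
        null_pair.append(sorted(table.pair_scores.values(), reverse=True))
    return null_gene, null_pair


def empirical_fdr(observed: dict, null_runs: list[list[float]]) -> dict:
    """Empirical FDR per observed feature score against a permutation null.

    FDR(s) = [mean over null runs of #{null scores >= s}] / #{observed >= s},
    clipped to [0, 1] and made monotone non-increasing in s by a step-down
    pass (a higher score can never have a larger FDR than a lower one).
    """
    if not observed:
        raise ValueError("empty observed score set")
    if not null_runs:
        raise ValueError("need at least one null run")
    feats = list(observed)
    scores = np.array([observed[f] for f in feats], dtype=float)
    obs_sorted = np.sort(scores)
    null_all = np.sort(np.concatenate([np.asarray(r, dtype=float) for r in null_runs]))
    n_runs = len(null_runs)

    order = np.argsort(scores)  # ascending
    raw = np.empty(scores.size)
    for rank, idx in enumerate(order):
        s = scores[idx]
        n_obs_ge = scores.size - np.searchsorted(obs_sorted, s, side="left")
        n_null_ge = null_all.size - np.searchsorted(null_all, s, side="left")
        raw[rank] = min(1.0, (n_null_ge / n_runs) / n_obs_ge)
    # step-down to a q-value: the best achievable FDR among rejection regions
    # containing the feature, i.e. a running minimum over ascending scores
    adj = np.minimum.accumulate(raw)
    return {feats[idx]: float(adj[rank]) for rank, idx in enumerate(order)}


def pair_beats_singles(rec: PairRecord, min_trees: int = 5) -> float:
    """One-sided p-value that the pair's per-tree error increase exceeds the
    best single member's increase in the same trees (Wilcoxon signed-rank).

    Pairs with fewer than ``min_trees`` qualifying trees, or with identical
    pair and member increases everywhere, get p = 1.
    """
    if len(rec.pair_increase) < min_trees:
        logger.debug("pair %s has only %d qualifying trees", set(rec.pair), len(rec.pair_increase))
        return 1.0
    pair_inc = np.asarray(rec.pair_increase)
    members = list(rec.member_increase.values())
    best_single = np.maximum(np.asarray(members[0]), np.asarray(members[1]))
    diff = pair_inc - best_single
    if np.all(diff == 0):
        return 1.0
    stat = wilcoxon(pair_inc, best_single, alternative="greater", zero_method="zsplit")
    return float(stat.pvalue)


def pair_beats_singles_batch(
    records: dict[frozenset, PairRecord], alpha: float = 0.05, min_trees: int = 5
) -> dict[frozenset, tuple[float, float, bool]]:
    """Benjamini-Hochberg over all candidate pairs; pair -> (p, q, significant)."""
    keys = list(records)
    if not keys:
        return {}
    pvals = np.array([pair_beats_singles(records[k], min_trees=min_trees) for k in keys])
    reject, qvals, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    return {k: (float(p), float(q), bool(r)) for k, p, q, r in zip(keys, pvals, qvals, reject)}


@dataclass
class DecisionModule:
    genes: set[str]
    internal_pairs: set[frozenset]
    representative_tree: int | None  # index into forest.trees, or None


def _tree_sets(forest: Forest, genes: set[str], pairs: set[frozenset]) -> dict:
    """Feature -> set of tree indices in which the feature appears."""
    per_tree_genes = [tree_genes(t) for t in forest.trees]
    sets: dict = {}
    for g in genes:
        sets[g] = {i for i, tg in enumerate(per_tree_genes) if g in tg}
    for p in pairs:
        a, b = sorted(p)
        sets.setdefault(a, {i for i, tg in enumerate(per_tree_genes) if a in tg})
        sets.setdefault(b, {i for i, tg in enumerate(per_tree_genes) if b in tg})
    return sets


def consensus_modules(
    significant_genes: set[str],
    significant_pairs: set[frozenset],
    forest: Forest,
    net: ProteinNetwork,
    data: LabeledExpression | None = None,
    damping: float = 0.5,
    max_iter: int = 1000,
    random_state: int = 0,
) -> list[DecisionModule]:
    """Cluster significant features into decision modules.

    Gene-gene similarity is the Jaccard index of the tree sets containing
    each gene; clustering is affinity propagation with preference = median
    similarity. Clusters whose genes are disconnected in the network are
    split into their connected components, so every reported module induces
    a connected subgraph. Each module is assigned the most accurate tree
    (by OOB error, if expression data is supplied) whose gene set is
    contained in the module.
    """
    universe = set(significant_genes)
    for p in significant_pairs:
        universe |= set(p)
    if not universe:
        raise ValueError("no significant features to cluster")
    genes = sorted(universe)
    tree_sets = _tree_sets(forest, universe, significant_pairs)

    n = len(genes)
    sim = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            a, b = tree_sets[genes[i]], tree_sets[genes[j]]
            union = len(a | b)
            sim[i, j] = sim[j, i] = (len(a & b) / union) if union else 0.0
    if n == 1:
        labels = np.array([0])
    else:
        # preference defaults to the median similarity (sklearn's convention)
        ap = AffinityPropagation(
            affinity="precomputed", damping=damping,
            max_iter=max_iter, random_state=random_state,
        )
        labels = ap.fit_predict(sim)
        if (labels < 0).any():  # non-convergence: fall back to singletons
            logger.warning("affinity propagation did not converge; using singleton clusters")
            labels = np.arange(n)

    clusters: dict[int, set[str]] = {}
    for g, lab in zip(genes, labels):
        clusters.setdefault(int(lab), set()).add(g)

    import networkx as nx

    idx = {g: i for i, g in enumerate(genes)}
    modules: list[DecisionModule] = []
    for members in clusters.values():
        # genes that never co-appear in a tree (similarity 0) cannot share a
        # module: split the cluster along the positive-similarity graph first
        sim_graph = nx.Graph()
        sim_graph.add_nodes_from(members)
        for a in members:
            for b in members:
                if a < b and sim[idx[a], idx[b]] > 0:
                    sim_graph.add_edge(a, b)
        for sim_comp in nx.connected_components(sim_graph):
            sub = net.graph.subgraph(set(sim_comp) & net.nodes)
            components = [set(c) for c in nx.connected_components(sub)] if len(sub) else []
            leftover = set(sim_comp) - set(sub.nodes)
            components.extend({g} for g in sorted(leftover))
            for comp in components:
                pairs_in = {p for p in significant_pairs if set(p) <= comp}
                rep = _representative_tree(forest, comp, data)
                modules.append(DecisionModule(genes=comp, internal_pairs=pairs_in, representative_tree=rep))
    modules.sort(key=lambda m: (-len(m.genes), sorted(m.genes)))
    return modules


def _representative_tree(forest: Forest, module_genes: set[str], data: LabeledExpression | None) -> int | None:
    """Most accurate tree whose tested genes all lie inside the module."""
    best_idx, best_err = None, np.inf
    for i, t in enumerate(forest.trees):
        tg = tree_genes(t)
        if not tg or not tg <= module_genes:
            continue
        if data is not None:
            err = oob_error(forest, data, i)
            err = 1.0 if err is None else err
        else:
            err = 0.5
        if err < best_err or (err == best_err and best_idx is None):
            best_idx, best_err = i, err
    return best_idx


def importance_pipeline(
    data: LabeledExpression,
    net: ProteinNetwork,
    cfg: NGFConfig,
    n_null_runs: int = 100,
    tree_factor: int = 10,
    alpha: float = 0.05,
    seed: int = 0,
    forest: Forest | None = None,
) -> tuple[ImportanceTable, list[DecisionModule], Forest]:
    """Full pipeline: forest -> importances -> permutation null -> FDR ->
    pair-beats-singles filter -> consensus modules."""
    if forest is None:
        forest = build_forest(data, net, cfg)
    table = compute_importances(forest, data, derive_seed(seed, "imp"))
    table.null_gene_scores, table.null_pair_scores = null_distribution(
        data, net, cfg, n_runs=n_null_runs, tree_factor=tree_factor, seed=derive_seed(seed, "null")
    )
    table.fdr_gene = empirical_fdr(table.gene_scores, table.null_gene_scores)
    if table.pair_scores:
        table.fdr_pair = empirical_fdr(table.pair_scores, table.null_pair_scores)
    sig_genes = {g for g, q in table.fdr_gene.items() if q < alpha}
    beats = pair_beats_singles_batch(table.pair_records, alpha=alpha)
    sig_pairs = {
        p for p, q in table.fdr_pair.items()
        if q < alpha and beats.get(p, (1.0, 1.0, False))[2]
    }
    modules = (
        consensus_modules(sig_genes, sig_pairs, forest, net, data)
        if (sig_genes or sig_pairs)
        else []
    )
    return table, modules, forest
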