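"""Network-guided CART: grow a single decision tree constrained to a connected
subnetwork of the protein-protein interaction graph.

Each tree is grown on a bootstrap sample by recursive partitioning with the
Gini impurity criterion. The root gene is the best splitter among a uniform
random subset of size floor(sqrt(N)) of the measured network genes with at
least ``min_root_degree`` neighbors. At every subsequent node the candidate
set is drawn from the network neighborhood of genes already accepted into the
tree, each draw with probability proportional to the number of edges the
candidate shares with the current tree genes. A gene may appear at most once
on any root-to-leaf path. Recursion stops when the best achievable decrease
in weighted Gini impurity falls below ``epsilon``, the node is pure, or the
candidate pool is exhausted — so trees are deliberately shallow and each one
maps to a connected subnetwork and, for two-class problems, to a Boolean
logic function over its genes.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Callable, Iterator

import numpy as np

from .dataset import BootstrapSplit, LabeledExpression, derive_seed
from .graph_io import ProteinNetwork

__all__ = [
    "TreeNode",
    "NGFConfig",
    "gini_impurity",
    "best_split",
    "sample_root_candidates",
    "sample_expansion_candidates",
    "grow_tree",
    "predict_proba",
    "tree_genes",
    "iter_paths",
    "iter_leaves",
    "tree_predict_counts",
    "tree_to_json",
    "tree_from_json",
]


def _sqrt_rule(n: int) -> int:
    return max(1, int(math.isqrt(n)))


@dataclass
class NGFConfig:
    """Forest-level configuration.

    epsilon
        Minimum decrease in weighted Gini impurity required to accept a split
        (unnormalized scale; two-class impurity lives in [0, 0.5]).
    min_root_degree
        Minimum number of network neighbors required of a root gene; promotes
        growth from dense network regions.
    n_trees
        Ensemble size; stable importance rankings need large forests
        (>20,000 on real cohorts), tests use far fewer.
    candidate_size_rule
        Maps N (number of measured network genes) to the per-node candidate-set
        size; default floor(sqrt(N)), applied at the root and at every
        internal node alike.
    """

    epsilon: float = 0.01
    min_root_degree: int = 5
    n_trees: int = 20000
    candidate_size_rule: Callable[[int], int] = field(default=_sqrt_rule)
    seed: int = 0
    stratified_bootstrap: bool = False

    def __post_init__(self):
        if not self.epsilon > 0:
            raise ValueError("epsilon must be > 0")
        if self.min_root_degree < 0:
            raise ValueError("min_root_degree must be >= 0")
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")


@dataclass
class TreeNode:
    """Internal node (gene, threshold, children) or leaf (class_counts).

    Samples with expression strictly below the threshold go to the left child;
    values greater than or equal to the threshold go right. Leaf class_counts
    record the in-bag training samples that reached the leaf, per class.
    """

    gene: str | None = None
    threshold: float | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None
    class_counts: np.ndarray | None = None

    @property
    def is_leaf(self) -> bool:
        return self.gene is None


def gini_impurity(class_counts) -> float:
    """Gini index 1 - sum_c (n_c/n)^2 of a count vector; in [0, 1 - 1/C]."""
    counts = np.asarray(class_counts, dtype=float)
    if (counts < 0).any():
        raise ValueError("negative class counts")
    n = counts.sum()
    if n <= 0:
        raise ValueError("gini_impurity of an empty node is undefined")
    p = counts / n
    return float(1.0 - (p * p).sum())


def best_split(
    data: LabeledExpression,
    sample_idx: np.ndarray,
    candidates,
) -> tuple[str, float, float] | None:
    """Exhaustive best (gene, threshold) over candidates x midpoints.

    Thresholds are midpoints between consecutive distinct sorted expression
    values at the node. Returns (gene, threshold, gini_improvement) maximizing
    the unnormalized impurity decrease
    ``gini(parent) - (nL/n) gini(left) - (nR/n) gini(right)``,
    or None when no valid split exists. Ties are broken toward the
    lexicographically smallest gene ID, then the smallest threshold.
    """
    sample_idx = np.asarray(sample_idx)
    n = sample_idx.size
    if n < 2:
        return None
    y = data.y[sample_idx]
    C = data.n_classes
    parent_counts = np.bincount(y, minlength=C)
    if (parent_counts > 0).sum() < 2:
        return None  # pure node
    parent_gini = gini_impurity(parent_counts)
    onehot_total = parent_counts.astype(float)

    best: tuple[float, str, float] | None = None  # (improvement, gene, threshold)
    for gene in sorted(candidates):
        gi = data.gene_index.get(gene)
        if gi is None:
            raise KeyError(f"candidate gene {gene!r} not measured")
        v = data.values[gi, sample_idx]
        order = np.argsort(v, kind="stable")
        vs = v[order]
        ys = y[order]
        bounds = np.flatnonzero(vs[:-1] < vs[1:])
        if bounds.size == 0:
            continue  # constant gene at this node
        left = np.empty((bounds.size, C))  # class counts strictly below each threshold
        for c in range(C):
            left[:, c] = np.cumsum(ys == c)[bounds]
        right = onehot_total[None, :] - left
        n_left = left.sum(axis=1)
        n_right = n - n_left
        gini_left = 1.0 - ((left / n_left[:, None]) ** 2).sum(axis=1)
        gini_right = 1.0 - ((right / n_right[:, None]) ** 2).sum(axis=1)
        improvement = parent_gini - (n_left / n) * gini_left - (n_right / n) * gini_right
        k = int(np.argmax(improvement))  # first max -> smallest threshold
        imp = float(improvement[k])
        thr = float((vs[bounds[k]] + vs[bounds[k] + 1]) / 2.0)
        if best is None or imp > best[0]:
            best = (imp, gene, thr)
        # equal improvement: earlier (smaller) gene already held wins
    if best is None:
        return None
    return best[1], best[2], best[0]


def _measured_network_genes(net: ProteinNetwork, data: LabeledExpression) -> list[str]:
    return sorted(g for g in data.genes if net.has_node(g))


def sample_root_candidates(
    net: ProteinNetwork, measured: set[str], cfg: NGFConfig, seed: int
) -> set[str]:
    """Uniform sample of size min(floor(sqrt(N)), #eligible) root candidates.

    Eligible genes are measured network genes with degree >= min_root_degree;
    N counts all measured network genes.
    """
    pool = sorted(g for g in measured if net.has_node(g))
    eligible = [g for g in pool if net.degree(g) >= cfg.min_root_degree]
    if not eligible:
        raise ValueError(
            f"no measured gene has >= {cfg.min_root_degree} network neighbors; "
            "consider lowering min_root_degree"
        )
    m = min(cfg.candidate_size_rule(len(pool)), len(eligible))
    rng = np.random.default_rng(seed)
    picked = rng.choice(len(eligible), size=m, replace=False)
    return {eligible[i] for i in picked}


def sample_expansion_candidates(
    net: ProteinNetwork,
    tree_genes: set[str],
    path_genes: set[str],
    cfg: NGFConfig,
    seed: int,
    n_measured: int | None = None,
    measured: set[str] | None = None,
    adjacency: dict[str, set[str]] | None = None,
) -> set[str]:
    """Sequential weighted sample from the tree's network neighborhood.

    The pool is every measured neighbor of a gene already in the tree, minus
    genes on the current root-to-leaf path. Candidates are drawn one at a
    time without replacement, each draw with probability proportional to the
    candidate's number of edges into the current tree genes, until
    floor(sqrt(N)) distinct candidates are collected or the pool is empty.
    Each draw consumes one uniform variate and selects by prefix sum over the
    (sorted) remaining pool.
    """
    if not tree_genes:
        raise ValueError("tree_genes must be non-empty")
    if adjacency is None:
        adjacency = {}
    neigh = lambda g: adjacency[g] if g in adjacency else net.neighbors(g)
    pool_set: set[str] = set()
    for t in tree_genes:
        pool_set |= neigh(t)
    pool_set -= path_genes
    if measured is not None:
        pool_set &= measured
    pool = sorted(pool_set)
    if not pool:
        return set()
    if n_measured is None:
        n_measured = net.n_nodes()
    m = cfg.candidate_size_rule(n_measured)
    weights = [float(len(neigh(g) & tree_genes)) for g in pool]
    rng = np.random.default_rng(seed)
    chosen: set[str] = set()
    total = sum(weights)
    while pool and len(chosen) < m:
        r = rng.random() * total
        acc = 0.0
        for i, w in enumerate(weights):
            acc += w
            if r < acc:
                break
        chosen.add(pool.pop(i))
        total -= weights.pop(i)
    return chosen


def grow_tree(
    data: LabeledExpression,
    split: BootstrapSplit,
    net: ProteinNetwork,
    cfg: NGFConfig,
    seed: int,
    candidate_pool_hook: Callable[[int, set[str]], None] | None = None,
) -> TreeNode:
    """Grow one network-guided tree on the in-bag samples of ``split``.

    Nodes are expanded depth-first, left child first; each node receives a
    seed derived from (tree seed, node creation index), making the tree a
    pure function of its inputs. ``candidate_pool_hook``, if given, is called
    with (node_index, candidate_pool) for every node — used by tests to replay
    growth through an independent reference implementation.
    """
    measured = {g for g in data.genes if net.has_node(g)}
    if not measured:
        raise ValueError("no measured gene is present in the network")
    n_measured = len(measured)
    adjacency = {g: net.neighbors(g) & measured for g in measured}
    C = data.n_classes
    node_counter = [0]
    genes_in_tree: set[str] = set()

    def leaf(idx: np.ndarray) -> TreeNode:
        return TreeNode(class_counts=np.bincount(data.y[idx], minlength=C))

    def try_split(idx: np.ndarray, candidates: set[str]) -> tuple[str, float, float] | None:
        if idx.size < 2 or not candidates:
            return None
        found = best_split(data, idx, candidates)
        if found is None or found[2] < cfg.epsilon:
            return None
        return found

    def build(idx: np.ndarray, path_genes: set[str]) -> TreeNode:
        node_id = node_counter[0]
        node_counter[0] += 1
        if node_id == 0:
            cands = sample_root_candidates(net, measured, cfg, derive_seed(seed, "root"))
        else:
            if idx.size < 2 or len(np.unique(data.y[idx])) < 2:
                return leaf(idx)
            cands = sample_expansion_candidates(
                net,
                genes_in_tree,
                path_genes,
                cfg,
                derive_seed(seed, "expand", node_id),
                n_measured=n_measured,
                measured=measured,
                adjacency=adjacency,
            )
        if candidate_pool_hook is not None:
            candidate_pool_hook(node_id, set(cands))
        found = try_split(idx, cands)
        if found is None:
            return leaf(idx)
        gene, thr, _ = found
        genes_in_tree.add(gene)
        v = data.values[data.gene_index[gene], idx]
        left_idx = idx[v < thr]
        right_idx = idx[v >= thr]
        node = TreeNode(gene=gene, threshold=thr)
        node.left = build(left_idx, path_genes | {gene})
        node.right = build(right_idx, path_genes | {gene})
        return node

    return build(np.asarray(split.in_bag), set())


# ---------------------------------------------------------------------------
# Tree queries / prediction


def tree_genes(tree: TreeNode) -> set[str]:
    """Set of genes tested anywhere in the tree."""
    out: set[str] = set()
    stack = [tree]
    while stack:
        node = stack.pop()
        if not node.is_leaf:
            out.add(node.gene)
            stack.extend((node.left, node.right))
    return out


def iter_leaves(tree: TreeNode) -> Iterator[TreeNode]:
    stack = [tree]
    while stack:
        node = stack.pop()
        if node.is_leaf:
            yield node
        else:
            stack.extend((node.right, node.left))


def iter_paths(tree: TreeNode) -> Iterator[tuple[list[tuple[str, float, bool]], TreeNode]]:
    """Yield (path, leaf) pairs; each path step is (gene, threshold, went_right)."""

    def walk(node, path):
        if node.is_leaf:
            yield path, node
        else:
            yield from walk(node.left, path + [(node.gene, node.threshold, False)])
            yield from walk(node.right, path + [(node.gene, node.threshold, True)])

    yield from walk(tree, [])


def predict_proba(tree: TreeNode, sample_values: dict[str, float]) -> np.ndarray:
    """Leaf class proportions for one sample given its gene -> expression map."""
    node = tree
    while not node.is_leaf:
        if node.gene not in sample_values:
            raise KeyError(f"sample is missing a value for gene {node.gene!r} on its path")
        node = node.right if sample_values[node.gene] >= node.threshold else node.left
    counts = node.class_counts.astype(float)
    return counts / counts.sum()


def tree_predict_counts(
    tree: TreeNode,
    data: LabeledExpression,
    sample_idx: np.ndarray,
    override: dict[str, np.ndarray] | None = None,
) -> np.ndarray:
    """Route samples down the tree; return each sample's leaf class counts.

    ``override`` maps gene -> replacement expression vector aligned with
    ``sample_idx`` (used for permutation importance).
    """
    sample_idx = np.asarray(sample_idx)
    out = np.empty((sample_idx.size, tree_n_classes(tree)), dtype=float)

    def gene_vector(gene: str, pos: np.ndarray) -> np.ndarray:
        if override is not None and gene in override:
            return override[gene][pos]
        return data.values[data.gene_index[gene], sample_idx[pos]]

    def walk(node: TreeNode, pos: np.ndarray):
        if pos.size == 0:
            return
        if node.is_leaf:
            out[pos] = node.class_counts
            return
        v = gene_vector(node.gene, pos)
        go_right = v >= node.threshold
        walk(node.left, pos[~go_right])
        walk(node.right, pos[go_right])

    walk(tree, np.arange(sample_idx.size))
    return out


def tree_n_classes(tree: TreeNode) -> int:
    node = tree
    while not node.is_leaf:
        node = node.left
    return node.class_counts.size


# ---------------------------------------------------------------------------
# Serialization (stable key order)


def _node_to_dict(node: TreeNode) -> dict:
    if node.is_leaf:
        return {"counts": [int(c) for c in node.class_counts]}
    return {
        "gene": node.gene,
        "threshold": node.threshold,
        "left": _node_to_dict(node.left),
        "right": _node_to_dict(node.right),
    }


def _node_from_dict(d: dict) -> TreeNode:
    if "counts" in d:
        return TreeNode(class_counts=np.asarray(d["counts"], dtype=np.int64))
    return TreeNode(
        gene=d["gene"],
        threshold=d["threshold"],
        left=_node_from_dict(d["left"]),
        right=_node_from_dict(d["right"]),
    )


def tree_to_json(tree: TreeNode) -> str:
    return json.dumps(_node_to_dict(tree))


def tree_from_json(s: str) -> TreeNode:
    return _node_from_dict(json.loads(s))
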