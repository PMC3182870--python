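"""Ensemble construction, out-of-bag bookkeeping, voting and occurrence tallies.

Each tree is grown independently from its own derived seed, so the forest is
a pure function of (data, network, config) and identical regardless of build
order. Per-tree out-of-bag (OOB) samples — those never drawn into the tree's
bootstrap — provide unbiased per-tree error estimates that drive permutation
importance downstream.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .dataset import BootstrapSplit, LabeledExpression, bootstrap, derive_seed
from .graph_io import ProteinNetwork
from .tree import (
    NGFConfig,
    TreeNode,
    grow_tree,
    tree_from_json,
    tree_genes,
    tree_predict_counts,
    tree_to_json,
)

logger = logging.getLogger("ngforest")

__all__ = ["Forest", "build_forest", "predict_proba_forest", "predict_scores", "class_calls",
           "oob_error", "forest_oob_error", "save_forest", "load_forest"]


@dataclass
class Forest:
    trees: list[TreeNode]
    splits: list[BootstrapSplit]
    config: NGFConfig
    classes: list[str]
    target_class: str
    gene_occurrence: dict[str, int] = field(default_factory=dict)
    pair_occurrence: dict[frozenset, int] = field(default_factory=dict)

    @property
    def n_trees(self) -> int:
        return len(self.trees)

    @property
    def target_code(self) -> int:
        return self.classes.index(self.target_class)

    def genes_of_tree(self, i: int) -> set[str]:
        return tree_genes(self.trees[i])

    def trees_using(self, gene: str) -> list[int]:
        return [i for i, t in enumerate(self.trees) if gene in tree_genes(t)]


def _tally(forest: Forest) -> None:
    forest.gene_occurrence = {}
    forest.pair_occurrence = {}
    for t in forest.trees:
        genes = sorted(tree_genes(t))
        for g in genes:
            forest.gene_occurrence[g] = forest.gene_occurrence.get(g, 0) + 1
        for a, b in itertools.combinations(genes, 2):
            key = frozenset((a, b))
            forest.pair_occurrence[key] = forest.pair_occurrence.get(key, 0) + 1


def build_forest(data: LabeledExpression, net: ProteinNetwork, cfg: NGFConfig) -> Forest:
    """Grow ``cfg.n_trees`` trees, each from its own derived bootstrap and seed."""
    trees: list[TreeNode] = []
    splits: list[BootstrapSplit] = []
    for i in range(cfg.n_trees):
        split = bootstrap(data, derive_seed(cfg.seed, "bootstrap", i), cfg.stratified_bootstrap)
        tree = grow_tree(data, split, net, cfg, seed=derive_seed(cfg.seed, "tree", i))
        trees.append(tree)
        splits.append(split)
        if (i + 1) % 1000 == 0:
            logger.info("grew %d/%d trees", i + 1, cfg.n_trees)
    forest = Forest(trees=trees, splits=splits, config=cfg,
                    classes=list(data.classes), target_class=data.target_class)
    _tally(forest)
    return forest


def predict_proba_forest(forest: Forest, sample_values: dict[str, float]) -> np.ndarray:
    """Unweighted mean of per-tree leaf class proportions for one sample."""
    from .tree import predict_proba

    probs = np.zeros(len(forest.classes))
    for t in forest.trees:
        probs += predict_proba(t, sample_values)
    return probs / forest.n_trees


def predict_scores(
    forest: Forest, data: LabeledExpression, sample_idx: np.ndarray | None = None
) -> np.ndarray:
    """Per-sample forest probabilities, shape (n_samples, n_classes).

    The continuous target-class column is the score used for ROC analysis;
    class calls use argmax with ties broken toward the target class.
    """
    if sample_idx is None:
        sample_idx = np.arange(data.n_samples)
    sample_idx = np.asarray(sample_idx)
    acc = np.zeros((sample_idx.size, len(forest.classes)))
    for t in forest.trees:
        counts = tree_predict_counts(t, data, sample_idx)
        acc += counts / counts.sum(axis=1, keepdims=True)
    return acc / forest.n_trees


def class_calls(counts_or_probs: np.ndarray, target_code: int) -> np.ndarray:
    """Deterministic class call per row: argmax, ties broken toward the target class."""
    arr = np.asarray(counts_or_probs, dtype=float)
    best = arr.max(axis=1)
    calls = np.where(arr[:, target_code] == best, target_code, arr.argmax(axis=1))
    return calls


def oob_error(
    forest: Forest,
    data: LabeledExpression,
    tree_index: int,
    value_override: dict[str, np.ndarray] | None = None,
) -> float | None:
    """Per-tree OOB misclassification fraction.

    ``value_override`` maps gene -> replacement vector aligned with the
    tree's OOB index array (used to permute a gene's measurements). Trees
    with an empty OOB set return None.
    """
    if not 0 <= tree_index < forest.n_trees:
        raise IndexError(f"tree index {tree_index} out of range")
    oob = forest.splits[tree_index].out_of_bag
    if oob.size == 0:
        logger.debug("tree %d has no out-of-bag samples", tree_index)
        return None
    counts = tree_predict_counts(forest.trees[tree_index], data, oob, override=value_override)
    calls = class_calls(counts, forest.target_code)
    return float(np.mean(calls != data.y[oob]))


def forest_oob_error(forest: Forest, data: LabeledExpression) -> float:
    """Forest-level OOB error: each sample voted on only by trees for which
    it is out-of-bag; samples that are in-bag everywhere are skipped."""
    n = data.n_samples
    acc = np.zeros((n, len(forest.classes)))
    n_votes = np.zeros(n)
    for t, split in zip(forest.trees, forest.splits):
        oob = split.out_of_bag
        if oob.size == 0:
            continue
        counts = tree_predict_counts(t, data, oob)
        acc[oob] += counts / counts.sum(axis=1, keepdims=True)
        n_votes[oob] += 1
    voted = n_votes > 0
    calls = class_calls(acc[voted], forest.target_code)
    return float(np.mean(calls != data.y[voted]))


# ---------------------------------------------------------------------------
# Serialization


def save_forest(forest: Forest, path) -> None:
    payload = {
        "classes": forest.classes,
        "target_class": forest.target_class,
        "config": {
            "epsilon": forest.config.epsilon,
            "min_root_degree": forest.config.min_root_degree,
            "n_trees": forest.config.n_trees,
            "seed": forest.config.seed,
        },
        "trees": [json.loads(tree_to_json(t)) for t in forest.trees],
        "in_bag": [s.in_bag.tolist() for s in forest.splits],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_forest(path, n_samples: int | None = None) -> Forest:
    with open(path) as fh:
        payload = json.load(fh)
    trees = [tree_from_json(json.dumps(d)) for d in payload["trees"]]
    splits = []
    for bag in payload["in_bag"]:
        bag = np.asarray(bag, dtype=np.intp)
        total = n_samples if n_samples is not None else bag.size
        splits.append(BootstrapSplit(in_bag=bag, out_of_bag=np.setdiff1d(np.arange(total), bag)))
    cfgd = payload["config"]
    cfg = NGFConfig(epsilon=cfgd["epsilon"], min_root_degree=cfgd["min_root_degree"],
                    n_trees=cfgd["n_trees"], seed=cfgd["seed"])
    forest = Forest(trees=trees, splits=splits, config=cfg,
                    classes=payload["classes"], target_class=payload["target_class"])
    _tally(forest)
    return forest
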