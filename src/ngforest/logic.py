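"""Boolean logic extraction from decision trees.

For two-class problems a decision tree over binarized gene activities is a
Boolean function: every root-to-leaf path is one row of a truth table, where
a gene tested with the >= branch on that path is "up", the < branch is
"down", and genes untested on the path are don't-cares. Rules are scored with
the Laplace accuracy (n_majority + 1)/(n_total + C), which shrinks
small-sample purity toward 1/C. Predictive gene pairs are placed into three
functional categories — "A AND B", "NOT A AND NOT B", "A AND NOT B" —
according to the expression signs with which the two genes vote for the
target phenotype.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .forest import Forest
from .tree import TreeNode, iter_leaves, iter_paths, tree_genes

__all__ = [
    "TruthTable",
    "PairCategory",
    "tree_to_truth_table",
    "evaluate_truth_table",
    "format_rules",
    "truth_table_to_frame",
    "leaf_laplace",
    "laplace_tree_score",
    "laplace_forest_score",
    "pair_sign_category",
    "category_profile",
    "export_rules_multiclass",
    "CATEGORIES",
]

UP, DOWN, DONT_CARE = "up", "down", None
CATEGORIES = ("A AND B", "NOT A AND NOT B", "A AND NOT B")


@dataclass
class TruthTable:
    """Rows are (per-gene state, output class); one row per root-to-leaf path.

    States are 'up', 'down' or None (don't-care). Rows are mutually exclusive
    and exhaustive over assignments of up/down to the table's genes.
    """

    genes: list[str]
    rows: list[tuple[dict[str, str | None], str]]
    provenance: str | None = None


@dataclass
class PairCategory:
    pair: frozenset
    category: str
    signs: dict[str, str]  # gene -> '+' or '-'
    support: int


def _pre_order_genes(tree: TreeNode) -> list[str]:
    """Genes in order of first appearance (depth-first, left first)."""
    out: list[str] = []
    seen: set[str] = set()

    def walk(node: TreeNode):
        if node.is_leaf:
            return
        if node.gene not in seen:
            seen.add(node.gene)
            out.append(node.gene)
        walk(node.left)
        walk(node.right)

    walk(tree)
    return out


def _leaf_majority(counts: np.ndarray, classes: list[str], target_class: str | None) -> str:
    arr = np.asarray(counts, dtype=float)
    best = arr.max()
    if target_class is not None and arr[classes.index(target_class)] == best:
        return target_class
    return classes[int(arr.argmax())]


def tree_to_truth_table(
    tree: TreeNode,
    classes: list[str],
    target_class: str | None = None,
    class_rule=None,
    provenance: str | None = None,
) -> TruthTable:
    """One truth-table row per leaf of a two-class tree.

    ``class_rule`` maps a leaf node to its output class; the default is the
    majority in-bag class with ties broken toward ``target_class``. Genes not
    tested on a path are don't-care in that row.
    """
    if len(classes) != 2:
        raise ValueError(
            "truth tables are defined for two-class trees; "
            "use export_rules_multiclass for multi-class problems"
        )
    if class_rule is None:
        class_rule = lambda leaf: _leaf_majority(leaf.class_counts, classes, target_class)
    genes = _pre_order_genes(tree)
    rows: list[tuple[dict[str, str | None], str]] = []
    for path, leaf in iter_paths(tree):
        states: dict[str, str | None] = {g: DONT_CARE for g in genes}
        for gene, _thr, went_right in path:
            assert states[gene] is DONT_CARE, "gene tested twice on one path"
            states[gene] = UP if went_right else DOWN
        rows.append((states, class_rule(leaf)))
    return TruthTable(genes=genes, rows=rows, provenance=provenance)


def evaluate_truth_table(table: TruthTable, assignment: dict[str, str]) -> str:
    """Output class for a full up/down assignment to the table's genes."""
    matches = [
        out
        for states, out in table.rows
        if all(s is DONT_CARE or assignment[g] == s for g, s in states.items())
    ]
    if len(matches) != 1:
        raise ValueError(f"assignment matched {len(matches)} rows; rows must partition the input space")
    return matches[0]


def format_rules(table: TruthTable, negate_prefix: str = "NOT ") -> list[str]:
    """Human-readable IF/THEN rules, one per row; don't-care genes are omitted."""
    rules = []
    for states, out in table.rows:
        lits = [
            (g if s == UP else f"{negate_prefix}{g}")
            for g, s in states.items()
            if s is not DONT_CARE
        ]
        cond = " AND ".join(lits) if lits else "TRUE"
        rules.append(f"IF {cond} THEN {out}")
    return rules


def truth_table_to_frame(table: TruthTable) -> pd.DataFrame:
    """TSV-friendly view: one row per path, columns = genes + output."""
    recs = []
    for states, out in table.rows:
        rec = {g: ("*" if s is DONT_CARE else s) for g, s in states.items()}
        rec["output"] = out
        recs.append(rec)
    return pd.DataFrame(recs, columns=table.genes + ["output"])


def export_rules_multiclass(tree: TreeNode, classes: list[str]) -> list[str]:
    """Decision rules (path conjunctions over thresholds) for any class count."""
    rules = []
    for path, leaf in iter_paths(tree):
        lits = [
            f"{g} {'>=' if right else '<'} {thr:g}" for g, thr, right in path
        ]
        out = classes[int(np.argmax(leaf.class_counts))]
        cond = " AND ".join(lits) if lits else "TRUE"
        rules.append(f"IF {cond} THEN {out}")
    return rules


# ---------------------------------------------------------------------------
# Laplace accuracy


def leaf_laplace(class_counts, n_classes: int | None = None) -> float:
    """(n_majority + 1) / (n_total + C); equals 1/C on an empty leaf."""
    counts = np.asarray(class_counts, dtype=float)
    C = n_classes if n_classes is not None else counts.size
    return float((counts.max() + 1.0) / (counts.sum() + C))


def laplace_tree_score(tree: TreeNode) -> float:
    """Mean leaf Laplace score weighted by leaf training-sample counts."""
    scores, weights = [], []
    for leaf in iter_leaves(tree):
        n = float(leaf.class_counts.sum())
        scores.append(leaf_laplace(leaf.class_counts))
        weights.append(n)
    total = sum(weights)
    if total == 0:
        return float(np.mean(scores))
    return float(np.average(scores, weights=weights))


def laplace_forest_score(forest: Forest, tree_indices=None) -> float:
    """Unweighted mean of per-tree Laplace scores (optionally over a subset)."""
    idx = range(forest.n_trees) if tree_indices is None else tree_indices
    vals = [laplace_tree_score(forest.trees[i]) for i in idx]
    if not vals:
        raise ValueError("no trees to score")
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# Functional pair categories


def _sign_multiset_category(signs: dict[str, str]) -> str:
    n_plus = sum(1 for s in signs.values() if s == "+")
    if n_plus == 2:
        return "A AND B"
    if n_plus == 0:
        return "NOT A AND NOT B"
    return "A AND NOT B"


def pair_sign_category(
    forest: Forest, pair, target_class: str | None = None
) -> PairCategory | None:
    """Categorize a gene pair by the expression signs predicting the target class.

    Every root-to-leaf path (in trees containing both genes) that tests both
    genes and whose leaf majority is the target class contributes one vote
    per gene: '+' if the path took the >= branch at that gene, '-' for the <
    branch, weighted by the leaf's training-sample count. Each gene's final
    sign is the weighted majority ('+' on an exact tie); the category follows
    from the unordered sign pair. Returns None when no path qualifies.
    """
    a, b = sorted(pair)
    if a == b:
        raise ValueError("pair must consist of two distinct genes")
    if target_class is None:
        target_class = forest.target_class
    votes = {a: 0.0, b: 0.0}  # positive -> '+', negative -> '-'
    support = 0
    for t in forest.trees:
        tg = tree_genes(t)
        if not {a, b} <= tg:
            continue
        for path, leaf in iter_paths(t):
            tested = {g: right for g, _thr, right in path}
            if not {a, b} <= set(tested):
                continue
            if _leaf_majority(leaf.class_counts, forest.classes, forest.target_class) != target_class:
                continue
            w = float(leaf.class_counts.sum())
            support += 1
            for g in (a, b):
                votes[g] += w if tested[g] else -w
    if support == 0:
        return None
    signs = {g: ("+" if v >= 0 else "-") for g, v in votes.items()}
    return PairCategory(
        pair=frozenset((a, b)),
        category=_sign_multiset_category(signs),
        signs=signs,
        support=support,
    )


def category_profile(
    forest: Forest,
    scored_pairs: dict[frozenset, float],
    target_class: str | None = None,
    thresholds=None,
) -> pd.DataFrame:
    """Category fractions and mean Laplace accuracy as the pair-score cutoff tightens.

    For each (descending) cutoff, pairs scoring >= cutoff are categorized;
    fractions over the three categories sum to 1 among categorizable pairs
    and pairs with no qualifying path are counted separately. Accuracy is the
    unweighted mean Laplace score over trees containing at least one retained
    pair.
    """
    if not scored_pairs:
        raise ValueError("no scored pairs")
    if thresholds is None:
        uniq = sorted(set(scored_pairs.values()), reverse=True)
        thresholds = uniq[:10]
    per_tree_genes = [tree_genes(t) for t in forest.trees]
    cat_cache: dict[frozenset, PairCategory | None] = {}
    rows = []
    for cutoff in sorted(thresholds, reverse=True):
        retained = [p for p, s in scored_pairs.items() if s >= cutoff]
        counts = {c: 0 for c in CATEGORIES}
        n_uncat = 0
        for p in retained:
            if p not in cat_cache:
                cat_cache[p] = pair_sign_category(forest, p, target_class)
            cat = cat_cache[p]
            if cat is None:
                n_uncat += 1
            else:
                counts[cat.category] += 1
        n_cat = sum(counts.values())
        tree_idx = [
            i for i, tg in enumerate(per_tree_genes)
            if any(set(p) <= tg for p in retained)
        ]
        row = {"cutoff": cutoff, "n_pairs": len(retained), "n_uncategorized": n_uncat}
        for c in CATEGORIES:
            row[c] = counts[c] / n_cat if n_cat else np.nan
        row["laplace_accuracy"] = (
            laplace_forest_score(forest, tree_idx) if tree_idx else np.nan
        )
        rows.append(row)
    return pd.DataFrame(rows)
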