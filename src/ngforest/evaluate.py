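"""Cross-validated classification performance, cross-cohort rank
reproducibility, and Fisher's-exact functional enrichment.

The AUC is computed from the forest's continuous target-class score by the
rank (Mann-Whitney) statistic with midranks for ties, which equals the area
under the empirical ROC curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import fisher_exact, rankdata, spearmanr
from sklearn.model_selection import StratifiedKFold
from statsmodels.stats.multitest import multipletests

from .dataset import LabeledExpression, derive_seed
from .forest import Forest, build_forest, predict_scores
from .graph_io import ProteinNetwork
from .tree import NGFConfig

__all__ = [
    "CVResult",
    "auc_rank",
    "cross_validate",
    "rank_reproducibility",
    "fisher_enrichment",
    "fisher_enrichment_batch",
]


@dataclass
class CVResult:
    aucs: np.ndarray  # shape (repeats, folds)
    mean_auc: float
    std_auc: float
    sample_scores: np.ndarray  # per-sample target-class score averaged over repeats


def auc_rank(scores: np.ndarray, is_target: np.ndarray) -> float:
    """Area under the ROC curve by the rank statistic (ties get midranks)."""
    scores = np.asarray(scores, dtype=float)
    is_target = np.asarray(is_target, dtype=bool)
    n1 = int(is_target.sum())
    n0 = is_target.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC needs both classes present")
    ranks = rankdata(scores)  # midranks
    return float((ranks[is_target].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def cross_validate(
    data: LabeledExpression,
    net: ProteinNetwork,
    cfg: NGFConfig,
    folds: int = 5,
    repeats: int = 100,
    seed: int = 0,
) -> CVResult:
    """Stratified k-fold cross-validation of the forest's target-class score.

    Each repeat reshuffles the stratified fold assignment with its own derived
    seed; each fold trains a fresh forest on the remaining folds only.
    """
    counts = np.bincount(data.y)
    if counts.min() < folds:
        raise ValueError(
            f"smallest class has {counts.min()} samples; need >= {folds} for {folds}-fold CV"
        )
    aucs = np.zeros((repeats, folds))
    score_sum = np.zeros(data.n_samples)
    is_target = data.y == data.target_code
    for r in range(repeats):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=derive_seed(seed, "cv-fold", r))
        for f, (train_idx, test_idx) in enumerate(skf.split(np.zeros(data.n_samples), data.y)):
            train = LabeledExpression(
                genes=data.genes,
                samples=[data.samples[i] for i in train_idx],
                values=data.values[:, train_idx],
                labels=data.labels[train_idx],
                target_class=data.target_class,
            )
            fold_cfg = NGFConfig(
                epsilon=cfg.epsilon, min_root_degree=cfg.min_root_degree, n_trees=cfg.n_trees,
                candidate_size_rule=cfg.candidate_size_rule,
                seed=derive_seed(seed, "cv-forest", r * folds + f),
                stratified_bootstrap=cfg.stratified_bootstrap,
            )
            forest = build_forest(train, net, fold_cfg)
            probs = predict_scores(forest, data, test_idx)
            s = probs[:, forest.target_code]
            aucs[r, f] = auc_rank(s, is_target[test_idx])
            score_sum[test_idx] += s
    return CVResult(
        aucs=aucs,
        mean_auc=float(aucs.mean()),
        std_auc=float(aucs.mean(axis=1).std()),
        sample_scores=score_sum / repeats,
    )


def rank_reproducibility(
    forest_a: Forest, forest_b: Forest, top_n: int = 100
) -> tuple[float, int]:
    """Cross-cohort agreement of gene rankings by forest occurrence.

    Returns (Spearman correlation of occurrence counts over the union of
    genes appearing in either forest, size of the intersection of the top_n
    most abundant gene lists).
    """
    genes_a, genes_b = set(forest_a.gene_occurrence), set(forest_b.gene_occurrence)
    if not genes_a & genes_b:
        raise ValueError("forests have disjoint gene universes")
    union = sorted(genes_a | genes_b)
    occ_a = np.array([forest_a.gene_occurrence.get(g, 0) for g in union], dtype=float)
    occ_b = np.array([forest_b.gene_occurrence.get(g, 0) for g in union], dtype=float)
    rho = float(spearmanr(occ_a, occ_b).statistic)

    def top(forest: Forest) -> set[str]:
        ranked = sorted(forest.gene_occurrence.items(), key=lambda kv: (-kv[1], kv[0]))
        return {g for g, _ in ranked[:top_n]}

    return rho, len(top(forest_a) & top(forest_b))


def fisher_enrichment(
    module_genes: set[str], annotation_genes: set[str], background: set[str]
) -> tuple[float, float]:
    """One-sided (enrichment) Fisher's exact test on the 2x2 table of module
    membership vs annotation membership over the background gene set."""
    if not background:
        raise ValueError("empty background")
    module = set(module_genes)
    if not module <= set(background):
        raise ValueError("module genes must be a subset of the background")
    ann = set(annotation_genes) & set(background)
    a = len(module & ann)
    b = len(module - ann)
    c = len(ann - module)
    d = len(set(background) - module - ann)
    odds, p = fisher_exact([[a, b], [c, d]], alternative="greater")
    return float(odds), float(p)


def fisher_enrichment_batch(
    module_genes: set[str], annotations: dict[str, set[str]], background: set[str], alpha: float = 0.05
):
    """BH-corrected enrichment over a batch of annotation sets.

    Returns a list of (name, odds_ratio, p, q, significant), sorted by p.
    """
    import pandas as pd

    names = sorted(annotations)
    results = [fisher_enrichment(module_genes, annotations[n], background) for n in names]
    pvals = np.array([p for _odds, p in results])
    reject, qvals, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    frame = pd.DataFrame(
        {
            "annotation": names,
            "odds_ratio": [o for o, _p in results],
            "p_value": pvals,
            "q_value": qvals,
            "significant": reject,
        }
    ).sort_values("p_value", kind="stable", ignore_index=True)
    return frame
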