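# Methods

## Model

`ngforest` implements a network-guided variant of random forests for
classifying biological samples from gene expression, together with the
machinery that turns a trained ensemble into interpretable network biology.
The classifier is an ensemble of CART decision trees with one structural
constraint added: the set of genes tested anywhere in a tree must induce a
connected subgraph of a user-supplied protein–protein interaction network.
Each tree therefore corresponds to one candidate network module, and — for
two-class problems over binarized gene activities — to one Boolean logic
function describing how the module's component genes combine to determine
the phenotype.

### Tree induction

Each tree is grown on a bootstrap sample (drawn with replacement, same size
as the training set). Splits are chosen by exhaustive search over candidate
genes and thresholds, maximizing the decrease in weighted Gini impurity

    Δ = G(parent) − (n_L/n) G(left) − (n_R/n) G(right),   G = 1 − Σ_c p_c²

with thresholds at midpoints between consecutive distinct values (the CART
convention). Samples with expression below the threshold go left; at or
above the threshold go right. Growth stops at a node when the best
achievable Δ falls below ε, the node is pure or smaller than two samples,
or no candidate gene remains. ε is interpreted on the unnormalized Δ scale
(two-class impurity lives in [0, 0.5]); defaults of 0.01–0.02 are sensible
and 0.01 is the package default.

The network enters through candidate selection:

- The **root** is the best splitter among a uniform random subset of size
  ⌊√N⌋ of the measured network genes (N = number of measured network genes),
  restricted to genes with at least `min_root_degree` (default 5) network
  neighbors so that trees start in dense network regions.
- Every **internal node** draws its candidate set from the network
  neighborhood of the genes already accepted into the tree. Candidates are
  drawn sequentially without replacement, each draw with probability
  proportional to the number of edges the candidate shares with the current
  tree genes, until ⌊√N⌋ distinct candidates are collected or the
  neighborhood is exhausted. Weights are recomputed at each node from the
  genes accepted so far (the tree, not the candidate pool, grows between
  nodes). The same ⌊√N⌋ size rule is used at the root and internally.
- A gene may appear at most once on any root-to-leaf path; it may appear in
  two sibling branches.

Nodes are expanded depth-first, left child first, and every random draw is
keyed by (master seed, purpose tag, index) through a hash-based derivation
rule, so forests are bit-reproducible and independent of build order.
Setting the network to the complete graph and `min_root_degree = 0` reduces
the procedure exactly to a random-subspace CART forest; this reduction is
asserted split-by-split against an independent reference implementation in
the test suite.

### Prediction

A sample is routed down each tree; the tree votes with the class proportions
of the training samples in its leaf, and the forest score is the unweighted
mean over trees. Class calls take the argmax with ties broken toward the
designated target class (the positive / aggressive phenotype); the
continuous target-class score supports ROC analysis and threshold tuning.

## Importance, null model and modules

Per-tree out-of-bag (OOB) samples give an unbiased error estimate for each
tree. The importance of a gene is the mean increase in per-tree OOB
misclassification error when the gene's OOB measurements are randomly
permuted; trees that never test the gene contribute exactly 0 to the mean,
and trees with an empty OOB set are skipped. Pair importance permutes both
genes of a pair within trees containing both; each gene is permuted
independently by default (destroying both marginal signals and the joint
pattern — a joint-permutation variant is available via a flag). For ranking,
the pair mean extends the zero-contribution convention to all trees; the
pair-versus-singles test uses means conditional on the co-occurring trees.

Significance is assessed against an empirical null obtained by re-running
the entire pipeline (forest plus importance) on data with permuted class
labels, 100 runs by default. Null forests default to one tenth of the
observed forest's tree count (logged, configurable): the null sweep is by
far the dominant cost and the top-score null is estimated well at reduced
tree counts, which the calibration tests verify at matched scale. The
empirical FDR of an observed score s is the mean number of null scores ≥ s
per run divided by the number of observed scores ≥ s, clipped to [0, 1] and
converted to a q-value by a running minimum over ascending scores. The
pooled-across-runs null is used; a max-statistic variant can be obtained by
passing per-run maxima. A pair is reported only if, additionally, its
per-tree error increase exceeds the larger of its members' increases in the
same trees by a one-sided Wilcoxon signed-rank test, Benjamini–Hochberg
corrected across candidate pairs (the statistical form of this check was an
open design point; the paired one-sided signed-rank test is the natural
nonparametric choice for per-tree paired increases).

Significant genes and pair members are clustered into **consensus decision
modules** by affinity propagation on the Jaccard similarity of the sets of
trees in which each gene appears. We use scikit-learn's affinity propagation
with its default preference (median similarity) and damping 0.5; damping
0.9 was found to converge to degenerate fixed points on small similarity
matrices (merging zero-similarity genes, splitting high-similarity pairs),
so the lighter damping is the default and both knobs remain exposed.
Clusters are post-processed so that genes with zero co-occurrence never
share a module and each reported module induces a connected subgraph
(disconnected clusters are split into components). Each module is assigned
a representative tree: the lowest-OOB-error tree whose gene set lies inside
the module.

## Logic extraction

For two-class problems each tree maps to a truth table with one row per
root-to-leaf path: a gene tested with the ≥ branch is "up", the < branch
"down", and genes untested on that path are don't-cares; the row's output is
the leaf's majority class (ties toward the target class). Rows are mutually
exclusive and exhaustive by construction, which the tests verify by
exhaustive enumeration. Multi-class trees are exported as threshold rules
instead, since the Boolean mapping is specific to binary activities and two
classes. Rule accuracy uses the Laplace score (n_majority + 1)/(n_total + C)
per leaf, averaged over leaves with training-count weights within a tree and
unweighted across trees.

Gene pairs are assigned to one of three functional categories — "A AND B",
"NOT A AND NOT B", "A AND NOT B" — from the expression signs with which the
two genes vote for the target class: every target-class path testing both
genes contributes a +/− vote per gene (≥ branch = +), weighted by the leaf's
training count, and each gene's sign is the weighted majority (ties to +).
Weighted-majority aggregation across conflicting paths was an open design
point and is flagged as such. The category profile reports the mix of the
three categories and the mean Laplace accuracy as the pair-score cutoff
tightens.

## Synthetic benchmark

Because the original cohort data are external, the package ships a
first-class generator of planted-logic benchmarks. A scenario plants one or
more connected modules (cliques, padded with random background edges so
every planted gene passes the root-degree filter) inside an Erdős–Rényi
background network (a scale-free option exists since real PPI degree
distributions are heavy-tailed). Each planted gene has a latent Bernoulli(½)
up/down state per sample (optionally correlated within a module); the class
label is a specified Boolean function of those states (OR across modules
when several are planted); observed expression is baseline + Δ·state +
N(0, 1) with pure N(0, 1) noise genes. Δ is therefore the effect size in
units of the noise standard deviation.

The default study conditions are Δ = 3, 100 samples per class, a planted
two-gene "A AND NOT B" module and 30 noise genes. The generator reproduces
the structural features the method relies on (connected informative modules,
logic-determined labels, uninformative neighbors) but not microarray or
qRT-PCR platform artifacts, probe effects, correlated noise across genes, or
realistic class imbalance — so passing tests demonstrate correctness and
statistical calibration of the machinery, not expected performance on any
particular clinical cohort.

## Problem sizes and numerical choices

Test and acceptance runs use forests of 100–2,000 trees; production-scale
analyses should use the 20,000-tree default, as importance rankings
stabilize only in large ensembles. The reported calibration experiments use
50 label-permutation simulations with 6 null runs each, and planted-recovery
experiments use 20 independent scenario seeds. Tie-breaks are deterministic
everywhere (lexicographically smallest gene, then smallest threshold, for
equal-gain splits; target class for voting ties). Degenerate inputs are
resolved conservatively: pure or sub-two-sample nodes become leaves, trees
without OOB samples are excluded from importance averaging, pairs with
fewer than five co-occurring trees are never called significant, and an
empty expansion neighborhood simply terminates the branch.

## Known limitations

- Bootstrap is unstratified by default (a stratified flag exists); heavily
  imbalanced classes may occasionally produce single-class bags.
- The ε threshold compares unnormalized Gini decrease; data with very many
  classes would need a rescaled ε.
- Affinity propagation can fail to converge on pathological similarity
  matrices; the implementation then falls back to singleton clusters and
  warns.
- Enrichment analysis consumes user-supplied gene sets only; no annotation
  databases are bundled or queried.
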